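"""Thermodynamic conversions between dissociation constants and standard
binding free energies.

The binding energy is reported as the positive magnitude

    dG0 = -R T ln(Kd / 1 M)

relative to a 1 M standard state, so that tighter binding gives a larger
positive number (the sign convention used throughout pull-down energetics:
a micromolar interaction at 20 degC is ~8 kcal/mol). Kd must therefore be
supplied in molar.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidAffinityError, InvalidInputError

#: Gas constant in kcal / (mol K).
GAS_CONSTANT_KCAL: float = 1.9872e-3

#: Assay temperature: binding incubations at 20 degC.
DEFAULT_TEMPERATURE_K: float = 293.15


@dataclass(frozen=True)
class ReactionConditions:
    """Temperature and gas constant that fix the energy scale.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Default 293.15 K (20 degC, the
        incubation temperature of the assay).
    gas_constant : float
        Gas constant in kcal/(mol K). Default 1.9872e-3.
    """

    temperature: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.gas_constant > 0):
            raise InvalidInputError(f"gas_constant must be > 0, got {self.gas_constant}")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


#: Shared default conditions (20 degC).
STANDARD_CONDITIONS = ReactionConditions()


def dg_from_kd(kd: float, conditions: ReactionConditions = STANDARD_CONDITIONS) -> float:
    """Standard binding free energy magnitude -RT ln(Kd) in kcal/mol.

    Parameters
    ----------
    kd : float
        Dissociation constant in molar (1 M standard state). Must be > 0.

    Returns
    -------
    float
        Positive for kd < 1 M; 0 at the standard state.
    """
    if not (kd > 0) or not math.isfinite(kd):
        raise InvalidAffinityError(f"kd must be a positive finite molar value, got {kd}")
    return -conditions.rt * math.log(kd)


def kd_from_dg(delta_g: float, conditions: ReactionConditions = STANDARD_CONDITIONS) -> float:
    """Invert :func:`dg_from_kd`: Kd (molar) from a binding energy in kcal/mol."""
    if not math.isfinite(delta_g):
        raise InvalidInputError(f"delta_g must be finite, got {delta_g}")
    return math.exp(-delta_g / conditions.rt)


@dataclass(frozen=True)
class AffinityEstimate:
    """A dissociation constant with its equivalent binding energy.

    ``apparent`` marks estimates for constructs that can engage more than one
    partner simultaneously, where the single-site energy is a composite of
    several binding events.
    """

    kd: float
    delta_g: float
    apparent: bool = False
    label: str = ""
    conditions: ReactionConditions = field(default=STANDARD_CONDITIONS)

    def __post_init__(self) -> None:
        if not (self.kd > 0):
            raise InvalidAffinityError(f"kd must be > 0, got {self.kd}")
        expected = dg_from_kd(self.kd, self.conditions)
        scale = max(abs(expected), 1.0)
        if abs(self.delta_g - expected) > 1e-9 * scale:
            raise InvalidInputError(
                f"delta_g {self.delta_g} inconsistent with kd {self.kd} "
                f"(expected {expected}) under the given conditions"
            )

    @classmethod
    def from_kd(
        cls,
        kd: float,
        conditions: ReactionConditions = STANDARD_CONDITIONS,
        apparent: bool = False,
        label: str = "",
    ) -> "AffinityEstimate":
        return cls(
            kd=kd,
            delta_g=dg_from_kd(kd, conditions),
            apparent=apparent,
            label=label,
            conditions=conditions,
        )
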