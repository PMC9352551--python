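"""Generative model of complete supernatant-depletion experiments.

A scenario fixes the true binding energies, the solid-phase dilution
gradient, the receptor concentration, and the densitometry noise; the
forward equilibrium solvers then produce the true fraction bound at every
dilution, and the assay simulator turns those into band-intensity tables
with multiplicative log-normal densitometry noise (band intensities are
positive and staining error scales with signal), one control lane per
replicate gel, and optional additive leaching background.

Presets encode the study's measured scenarios (printed mean energies as
ground truth) for parameter-recovery testing, plus a two-site avidity
scenario and a solid-vs-soluble competition scenario.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .equilibrium import SiteClass, solve_multisite
from .errors import InvalidInputError
from .depletion import IntensityRecord, TitrationSeries
from .thermo import ReactionConditions, STANDARD_CONDITIONS, kd_from_dg


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of one synthetic experiment.

    ``site_classes`` lists the solid-phase ligand's independent site classes
    as (true binding energy in kcal/mol, sites per ligand molecule);
    concentrations are molar; ``densitometry_cv`` is the coefficient of
    variation of band quantification; one ``seed`` governs the scenario,
    with the per-replicate random streams derived deterministically from it
    (replicate k uses ``numpy.random.default_rng([seed, k])``).
    """

    site_classes: tuple[tuple[float, int], ...]
    label: str = "scenario"
    ligand_molecule_max: float = 1e-4
    n_dilutions: int = 10
    dilution_factor: float = 2.0
    r_total: float = 1e-7
    densitometry_cv: float = 0.05
    control_intensity_mean: float = 4000.0
    leaching_fraction: float = 0.0
    n_replicates: int = 6
    seed: int = 0
    conditions: ReactionConditions = field(default=STANDARD_CONDITIONS)
    apparent: bool = False
    competitor: tuple[float, float] | None = None  # (true dG0, total molar)

    def __post_init__(self) -> None:
        if len(self.site_classes) == 0:
            raise InvalidInputError("at least one site class is required")
        if not (self.ligand_molecule_max > 0 and self.r_total > 0):
            raise InvalidInputError("concentrations must be > 0")
        if self.n_dilutions < 1 or self.n_replicates < 1:
            raise InvalidInputError("n_dilutions and n_replicates must be >= 1")
        if not (self.dilution_factor > 1):
            raise InvalidInputError("dilution_factor must be > 1")
        if self.densitometry_cv < 0:
            raise InvalidInputError("densitometry_cv must be >= 0")
        if not (0.0 <= self.leaching_fraction < 1.0):
            raise InvalidInputError("leaching_fraction must be in [0, 1)")
        if not (self.control_intensity_mean > 0):
            raise InvalidInputError("control_intensity_mean must be > 0")

    @property
    def site_kds(self) -> tuple[float, ...]:
        """True per-site dissociation constants implied by the energies."""
        return tuple(kd_from_dg(dg, self.conditions) for dg, _ in self.site_classes)

    def ligand_series(self) -> tuple[float, ...]:
        """Descending 1:1-style serial dilution of the ligand molecule."""
        return tuple(
            self.ligand_molecule_max / self.dilution_factor**k
            for k in range(self.n_dilutions)
        )


def generate_titration(spec: ScenarioSpec) -> list[tuple[float, float]]:
    """Noiseless (ligand molecule concentration, true solid fraction bound)
    at every dilution, from the exact multisite equilibrium."""
    out = []
    for l_mol in spec.ligand_series():
        classes = [
            SiteClass(kd=kd, total_sites=l_mol * n_sites, phase="solid")
            for kd, (_, n_sites) in zip(spec.site_kds, spec.site_classes)
        ]
        if spec.competitor is not None:
            c_dg, c_total = spec.competitor
            classes.append(
                SiteClass(
                    kd=kd_from_dg(c_dg, spec.conditions),
                    total_sites=c_total,
                    phase="soluble",
                    label="competitor",
                )
            )
        state = solve_multisite(classes, spec.r_total)
        out.append((l_mol, state.fraction_receptor_bound_solid))
    return out


def simulate_assay(spec: ScenarioSpec) -> list[TitrationSeries]:
    """Band-intensity tables for every replicate of a scenario.

    Per replicate, the control lane intensity is
    ``control_intensity_mean * exp(e0)`` and each ligand lane is
    ``control_draw * (1 - F_b_true) * exp(e) + leaching_fraction *
    control_intensity_mean``, with e0, e independent N(0, ln(1 + cv)). The
    control draw is shared across that replicate's lanes, as one control
    lane serves a gel.
    """
    titration = generate_titration(spec)
    sigma = math.log1p(spec.densitometry_cv)
    series_list = []
    for k in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, k])
        eps0 = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        control_draw = spec.control_intensity_mean * math.exp(eps0)
        records = [
            IntensityRecord(
                experiment_id=spec.label,
                replicate_id=f"r{k + 1}",
                ligand_total=0.0,
                intensity=control_draw,
                is_control=True,
            )
        ]
        for l_mol, fb in titration:
            eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            intensity = (
                control_draw * (1.0 - fb) * math.exp(eps)
                + spec.leaching_fraction * spec.control_intensity_mean
            )
            records.append(
                IntensityRecord(
                    experiment_id=spec.label,
                    replicate_id=f"r{k + 1}",
                    ligand_total=l_mol,
                    intensity=intensity,
                    is_control=False,
                )
            )
        series_list.append(TitrationSeries(records=tuple(records)))
    return series_list


def paper_scenarios() -> dict[str, ScenarioSpec]:
    """Presets for the study's measured interactions.

    True energies are the printed replicate-set means (kcal/mol); energies
    for constructs that can engage more than one partner are apparent,
    composite values and the presets carry ``apparent=True``. Includes a
    two-site avidity scenario (two independent site classes of equal energy)
    and a solid-vs-soluble competition scenario.
    """
    single = lambda dg: ((dg, 1),)
    presets = {
        "pdz1-apm+par-complex": ScenarioSpec(
            site_classes=single(9.1), label="pdz1-apm+par-complex", apparent=True
        ),
        "pdz2+apkc-pbm": ScenarioSpec(
            site_classes=single(5.5), label="pdz2+apkc-pbm", apparent=True
        ),
        "pdz1-apm-dpdz2+par-complex": ScenarioSpec(
            site_classes=single(5.6), label="pdz1-apm-dpdz2+par-complex", apparent=True
        ),
        "pdz1-apm+par6-dpbm-complex": ScenarioSpec(
            site_classes=single(9.3), label="pdz1-apm+par6-dpbm-complex", apparent=True
        ),
        "pdz1-apm+apkc-kd-pbm": ScenarioSpec(
            site_classes=single(9.0), label="pdz1-apm+apkc-kd-pbm", apparent=True
        ),
        "pdz1-3+par-complex": ScenarioSpec(
            site_classes=single(9.3), label="pdz1-3+par-complex", apparent=True
        ),
        # Statistical-avidity null: two independent classes of equal energy.
        "avidity-two-site": ScenarioSpec(
            site_classes=((5.5, 1), (5.5, 1)), label="avidity-two-site", apparent=True
        ),
        # PDZ2 on the resin competing with soluble PDZ3 for the receptor.
        "pdz2-vs-pdz3-competition": ScenarioSpec(
            site_classes=single(5.5),
            label="pdz2-vs-pdz3-competition",
            competitor=(5.5, 5e-5),
            apparent=False,
        ),
    }
    return presets


def scenario_truth(spec: ScenarioSpec) -> dict:
    """Ground-truth record (sidecar) for recovery tests."""
    return {
        "label": spec.label,
        "true_dg_per_class": [dg for dg, _ in spec.site_classes],
        "sites_per_molecule": [n for _, n in spec.site_classes],
        "true_kd_per_class": list(spec.site_kds),
        "apparent": spec.apparent,
        "competitor": list(spec.competitor) if spec.competitor else None,
        "r_total": spec.r_total,
        "seed": spec.seed,
        "densitometry_cv": spec.densitometry_cv,
        "n_replicates": spec.n_replicates,
        "temperature": spec.conditions.temperature,
    }


def with_seed(spec: ScenarioSpec, seed: int) -> ScenarioSpec:
    """The same scenario with a different random seed."""
    return replace(spec, seed=seed)
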