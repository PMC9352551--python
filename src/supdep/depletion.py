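"""Quantification pipeline for supernatant-depletion binding assays.

The assay incubates a soluble "receptor" R with a resin-immobilized
"ligand" L and reads out the receptor band remaining in the supernatant at
equilibrium. With I_x the receptor band intensity at solid-phase
concentration x and I_0 the no-ligand control intensity,

    F_b = 1 - I_x / I_0

is the fraction of receptor bound. Because both species deplete, the
dissociation constant follows from mass action with [RL] = F_b [R]_total:

    Kd = ([L]_total - F_b [R]_total) ([R]_total - F_b [R]_total) / (F_b [R]_total)

and the binding energy is -RT ln Kd. The titration step picks the solid-
phase dilution giving 30-60% depletion (strong signal, far from
saturation); replicate measurements at that dilution are each converted to
an energy and then summarized.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bootstrap import BootstrapSettings, DEFAULT_SETTINGS, bootstrap_ci
from .errors import (
    AllBelowDetectionError,
    BelowDetectionError,
    DepletionInconsistencyError,
    InsufficientDataError,
    InvalidInputError,
    MissingControlError,
    SaturationError,
)
from .thermo import ReactionConditions, STANDARD_CONDITIONS, dg_from_kd

# Depletion band targeted by the titration step, and its midpoint.
FB_BAND = (0.3, 0.6)
FB_TARGET = 0.45

#: Potential partner-binding elements per construct. A single-site energy
#: reported for a construct with more than one element (or measured against
#: a multi-element partner) is a composite and is flagged "apparent".
BINDING_ELEMENT_REGISTRY: dict[str, int] = {
    "PDZ1-APM": 5,          # PDZ1, BR, PDZ2, PDZ3, APM
    "PDZ1-APM-dPDZ2": 4,
    "PDZ1-3": 4,
    "PDZ1-2": 3,
    "PDZ2-3": 2,
    "BR-PDZ2": 2,
    "BR-PDZ2-3": 3,
    "PDZ2": 1,
    "PDZ3": 1,
    "Crumbs-ICD": 1,
    "Par-complex": 3,       # aPKC PBM, aPKC kinase domain, Par-6 PBM
    "Par6-dPBM-complex": 2,
    "aPKC-KD-PBM": 2,
    "aPKC-PBM": 1,
    "Par6-CRIB-PDZ": 1,
}


_REGISTRY_FOLDED = {k.casefold(): v for k, v in BINDING_ELEMENT_REGISTRY.items()}


def is_apparent(*constructs: str) -> bool:
    """True when any named construct has more than one potential binding
    element in the registry (case-insensitive; unknown names count as
    single-element)."""
    return any(_REGISTRY_FOLDED.get(c.casefold(), 1) > 1 for c in constructs)


@dataclass(frozen=True)
class IntensityRecord:
    """One densitometry band measurement from a supernatant gel lane."""

    experiment_id: str
    replicate_id: str
    ligand_total: float
    intensity: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise InvalidInputError(f"intensity must be >= 0, got {self.intensity}")
        if self.ligand_total < 0:
            raise InvalidInputError(f"ligand_total must be >= 0, got {self.ligand_total}")
        if self.is_control != (self.ligand_total == 0.0):
            raise InvalidInputError(
                "is_control must be set exactly for ligand_total == 0 "
                f"(got is_control={self.is_control}, ligand_total={self.ligand_total})"
            )


@dataclass(frozen=True)
class TitrationSeries:
    """All lanes of one replicate: a descending ligand gradient plus exactly
    one no-ligand control."""

    records: tuple[IntensityRecord, ...]

    def __post_init__(self) -> None:
        controls = [r for r in self.records if r.is_control]
        points = [r for r in self.records if not r.is_control]
        if len(controls) != 1:
            raise InvalidInputError(
                f"series needs exactly one control record, got {len(controls)}"
            )
        if len(points) < 2:
            raise InvalidInputError(
                f"series needs >= 2 titration points, got {len(points)}"
            )
        ligs = [r.ligand_total for r in points]
        if any(b >= a for a, b in zip(ligs, ligs[1:])):
            raise InvalidInputError("ligand_total must be strictly decreasing")
        ids = {(r.experiment_id, r.replicate_id) for r in self.records}
        if len(ids) != 1:
            raise InvalidInputError("series must share one experiment and replicate id")

    @property
    def control(self) -> IntensityRecord:
        return next(r for r in self.records if r.is_control)

    @property
    def points(self) -> tuple[IntensityRecord, ...]:
        return tuple(r for r in self.records if not r.is_control)

    @property
    def experiment_id(self) -> str:
        return self.records[0].experiment_id

    @property
    def replicate_id(self) -> str:
        return self.records[0].replicate_id


@dataclass(frozen=True)
class DepletionMeasurement:
    """Fraction bound at one solid-phase concentration, for one replicate."""

    l_total: float
    r_total: float
    fraction_bound: float
    replicate_id: str = ""
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.l_total < 0 or not (self.r_total > 0):
            raise InvalidInputError(
                f"need l_total >= 0 and r_total > 0, got {self.l_total}, {self.r_total}"
            )
        if not self.below_detection and not (0.0 <= self.fraction_bound < 1.0):
            raise InvalidInputError(
                f"fraction_bound must be in [0, 1), got {self.fraction_bound}"
            )


@dataclass(frozen=True)
class EnergySummary:
    """Replicate-set binding energy statistics for one experiment."""

    n: int
    per_replicate_dg: tuple[float, ...]
    mean_dg: float
    sd_dg: float
    ci_low: float
    ci_high: float
    apparent: bool
    conditions: ReactionConditions
    below_detection_count: int = 0
    sd_defined: bool = True
    ci_method: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.n != len(self.per_replicate_dg):
            raise InvalidInputError("n must equal len(per_replicate_dg)")


def fraction_bound(i_x: float, i_0: float) -> float:
    """Fraction of receptor depleted from the supernatant, 1 - I_x/I_0.

    Negative raw values (densitometry noise on an undetectable interaction)
    are clipped to 0; use :func:`depletion_measurement` to also capture the
    below-detection flag.
    """
    if i_0 <= 0:
        raise MissingControlError(f"control intensity must be > 0, got {i_0}")
    if i_x < 0:
        raise InvalidInputError(f"intensity must be >= 0, got {i_x}")
    return max(0.0, 1.0 - i_x / i_0)


def depletion_measurement(
    i_x: float,
    i_0: float,
    l_total: float,
    r_total: float,
    replicate_id: str = "",
) -> DepletionMeasurement:
    """Build a :class:`DepletionMeasurement` from band intensities, flagging
    non-positive depletion as below detection."""
    raw = 1.0 - i_x / i_0 if i_0 > 0 else None
    fb = fraction_bound(i_x, i_0)
    return DepletionMeasurement(
        l_total=l_total,
        r_total=r_total,
        fraction_bound=fb,
        replicate_id=replicate_id,
        below_detection=(raw is not None and raw <= 0.0),
    )


def kd_from_depletion(m: DepletionMeasurement) -> float:
    """Ligand-depletion-corrected dissociation constant (molar).

    Substitutes [RL] = F_b [R]_total into Kd = [L][R]/[RL] with free
    concentrations [L] = [L]_total - [RL] and [R] = [R]_total - [RL].
    """
    fb = m.fraction_bound
    if m.below_detection or fb <= 0.0:
        raise BelowDetectionError(
            "fraction bound <= 0: interaction below the detection limit"
        )
    if fb >= 1.0:
        raise SaturationError("fraction bound >= 1: receptor fully depleted")
    complex_conc = fb * m.r_total
    if complex_conc >= m.l_total:
        raise DepletionInconsistencyError(
            f"bound complex {complex_conc:.3g} M >= total ligand {m.l_total:.3g} M"
        )
    return (m.l_total - complex_conc) * (m.r_total - complex_conc) / complex_conc


@dataclass(frozen=True)
class TitrationChoice:
    """The dilution selected for replication, with its band status."""

    index: int
    l_total: float
    fraction_bound: float
    in_band: bool


def select_titration_point(
    series: Sequence[tuple[float, float]],
    band: tuple[float, float] = FB_BAND,
    target: float = FB_TARGET,
) -> TitrationChoice:
    """Pick the dilution whose depletion lies in the 30-60% band.

    Among in-band points, the one closest to the band midpoint wins, ties
    going to the larger fraction bound (stronger signal). If no point is in
    band, the point nearest a band boundary is returned with
    ``in_band=False``.
    """
    if len(series) == 0:
        raise InvalidInputError("titration series is empty")
    lo, hi = band

    def key_for(fb: float) -> tuple[int, float, float]:
        if lo <= fb <= hi:
            return (0, abs(fb - target), -fb)  # in-band points always win
        return (1, lo - fb if fb < lo else fb - hi, -fb)

    best = None
    for i, (l_total, fb) in enumerate(series):
        key = key_for(fb)
        if best is None or key < best[0]:
            best = (key, i, l_total, fb)
    _, i, l_total, fb = best
    return TitrationChoice(
        index=i, l_total=float(l_total), fraction_bound=float(fb),
        in_band=bool(lo <= fb <= hi),
    )


def analyze_experiment(
    measurements: Iterable[DepletionMeasurement],
    conditions: ReactionConditions = STANDARD_CONDITIONS,
    apparent: bool = False,
    settings: BootstrapSettings = DEFAULT_SETTINGS,
    label: str = "",
) -> EnergySummary:
    """Per-replicate energies and their replicate-set summary.

    Each valid replicate is converted individually (Kd, then energy) before
    averaging; below-detection replicates are counted and excluded, never
    imputed. The CI of the mean is bootstrap-based (see
    :mod:`supdep.bootstrap`).
    """
    measurements = list(measurements)
    valid = [m for m in measurements if not m.below_detection and m.fraction_bound > 0.0]
    n_below = len(measurements) - len(valid)
    if not valid:
        raise AllBelowDetectionError(
            f"all {len(measurements)} replicates are below detection"
        )
    dgs = tuple(dg_from_kd(kd_from_depletion(m), conditions) for m in valid)
    mean = float(np.mean(dgs))
    if len(dgs) == 1:
        return EnergySummary(
            n=1, per_replicate_dg=dgs, mean_dg=mean, sd_dg=math.nan,
            ci_low=math.nan, ci_high=math.nan, apparent=apparent,
            conditions=conditions, below_detection_count=n_below,
            sd_defined=False, ci_method="", label=label,
        )
    sd = float(np.std(dgs, ddof=1))
    ci = bootstrap_ci(dgs, settings)
    return EnergySummary(
        n=len(dgs), per_replicate_dg=dgs, mean_dg=mean, sd_dg=sd,
        ci_low=ci.low, ci_high=ci.high, apparent=apparent,
        conditions=conditions, below_detection_count=n_below,
        sd_defined=True, ci_method=ci.method_used, label=label,
    )


def measurements_from_series(
    series_list: Sequence[TitrationSeries],
    r_total: float,
) -> tuple[list[DepletionMeasurement], TitrationChoice]:
    """Apply the titration protocol to a set of replicate series.

    The dilution is chosen once per experiment — as on the bench, where a
    pilot titration fixes the dilution and all replicates are run at it —
    using the replicate-averaged fraction bound per dilution. Each
    replicate's measurement at the chosen dilution is then returned.

    All series must share the same ligand gradient.
    """
    if len(series_list) == 0:
        raise InsufficientDataError("no replicate series supplied")
    ligands = [tuple(r.ligand_total for r in s.points) for s in series_list]
    if len(set(ligands)) != 1:
        raise InvalidInputError("replicate series have different ligand gradients")

    fb_matrix = []  # replicate x dilution, clipped at 0
    raw_matrix = []  # unclipped, to detect below-detection lanes
    for s in series_list:
        i0 = s.control.intensity
        if i0 <= 0:
            raise MissingControlError(
                f"replicate {s.replicate_id!r}: control intensity must be > 0"
            )
        fb_matrix.append([fraction_bound(p.intensity, i0) for p in s.points])
        raw_matrix.append([1.0 - p.intensity / i0 for p in s.points])

    mean_fb = np.mean(fb_matrix, axis=0)
    choice = select_titration_point(list(zip(ligands[0], mean_fb)))

    out = []
    for s, fbs, raws in zip(series_list, fb_matrix, raw_matrix):
        fb = fbs[choice.index]
        if fb >= 1.0:
            raise SaturationError(
                f"replicate {s.replicate_id!r}: receptor band fully depleted "
                "at the chosen dilution"
            )
        out.append(
            DepletionMeasurement(
                l_total=ligands[0][choice.index],
                r_total=r_total,
                fraction_bound=fb,
                replicate_id=s.replicate_id,
                below_detection=raws[choice.index] <= 0.0,
            )
        )
    return out, choice
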