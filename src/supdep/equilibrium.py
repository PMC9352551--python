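"""Exact forward mass-action equilibrium solvers with depletion of all
species.

These are the generative model behind the synthetic assay data and the
independent oracle against which the closed-form depletion estimator is
verified. Models:

* single site class (stable quadratic root),
* several independent site classes sharing one receptor (the avidity /
  statistical-multivalency null model, with no cooperativity term),
* solid-phase site vs soluble competitor (a two-class special case where
  only the solid class depletes the supernatant).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy.optimize import brentq

from .errors import InvalidInputError

Phase = Literal["solid", "soluble"]


@dataclass(frozen=True)
class SiteClass:
    """One class of independent, identical binding sites.

    ``total_sites`` is the total site concentration in molar (molecule
    concentration times sites per molecule for multivalent ligands).
    """

    kd: float
    total_sites: float
    label: str = ""
    phase: Phase = "solid"

    def __post_init__(self) -> None:
        if not (self.kd > 0):
            raise InvalidInputError(f"kd must be > 0, got {self.kd}")
        if self.total_sites < 0:
            raise InvalidInputError(f"total_sites must be >= 0, got {self.total_sites}")
        if self.phase not in ("solid", "soluble"):
            raise InvalidInputError(f"phase must be 'solid' or 'soluble', got {self.phase!r}")


@dataclass(frozen=True)
class EquilibriumState:
    """Solved occupancies for one receptor against a set of site classes."""

    free_receptor: float
    bound_per_class: tuple[float, ...]
    fraction_receptor_bound_total: float
    fraction_receptor_bound_solid: float
    r_total: float


def _state(classes: Sequence[SiteClass], free_r: float, r_total: float) -> EquilibriumState:
    bound = tuple(c.total_sites * free_r / (c.kd + free_r) for c in classes)
    total_bound = sum(bound)
    solid_bound = sum(b for b, c in zip(bound, classes) if c.phase == "solid")
    return EquilibriumState(
        free_receptor=free_r,
        bound_per_class=bound,
        fraction_receptor_bound_total=total_bound / r_total,
        fraction_receptor_bound_solid=solid_bound / r_total,
        r_total=r_total,
    )


def solve_single_site(kd: float, l_total: float, r_total: float) -> EquilibriumState:
    """Equilibrium of R + L <-> RL with depletion of both species.

    Uses the cancellation-free form of the quadratic root,
    ``bound = 2 l r / ((l + r + kd) + sqrt((l + r + kd)^2 - 4 l r))``,
    which stays accurate at small fractional occupancy.
    """
    if not (kd > 0):
        raise InvalidInputError(f"kd must be > 0, got {kd}")
    if l_total < 0 or not (r_total > 0):
        raise InvalidInputError(
            f"need l_total >= 0 and r_total > 0, got l_total={l_total}, r_total={r_total}"
        )
    if l_total == 0:
        return _state([SiteClass(kd=kd, total_sites=0.0)], r_total, r_total)
    s = l_total + r_total + kd
    disc = s * s - 4.0 * l_total * r_total
    bound = 2.0 * l_total * r_total / (s + math.sqrt(max(disc, 0.0)))
    free_r = r_total - bound
    state = _state([SiteClass(kd=kd, total_sites=l_total)], free_r, r_total)
    return state


def solve_multisite(classes: Sequence[SiteClass], r_total: float) -> EquilibriumState:
    """Equilibrium of one receptor against independent site classes.

    Solves the receptor conservation
    ``r_total = f + sum_i L_i f / (kd_i + f)`` for the free receptor ``f``
    by bracketed root-finding on ``[0, r_total]``; the left side is strictly
    increasing in ``f`` so the root is unique.
    """
    if len(classes) == 0:
        raise InvalidInputError("at least one site class is required")
    if not (r_total > 0):
        raise InvalidInputError(f"r_total must be > 0, got {r_total}")

    def conservation(f: float) -> float:
        return f + sum(c.total_sites * f / (c.kd + f) for c in classes) - r_total

    if conservation(r_total) <= 0.0:  # no binding capacity at all
        return _state(classes, r_total, r_total)
    free_r = brentq(
        conservation, 0.0, r_total, xtol=1e-30, rtol=8.9e-16, maxiter=200
    )
    return _state(classes, free_r, r_total)


def solve_competition(
    solid: SiteClass, competitor: SiteClass, r_total: float
) -> EquilibriumState:
    """Solid-phase site vs soluble competitor for one receptor.

    Complexes with the competitor stay in the supernatant, so only the solid
    class contributes to ``fraction_receptor_bound_solid`` — the quantity a
    supernatant-depletion readout sees.
    """
    if solid.phase != "solid":
        raise InvalidInputError("first site class must have phase 'solid'")
    if competitor.phase != "soluble":
        raise InvalidInputError("competitor site class must have phase 'soluble'")
    return solve_multisite([solid, competitor], r_total)


def apparent_affinity_dilute_limit(
    site_kds: Sequence[float], sites_per_molecule: Sequence[float] | None = None
) -> float:
    """Apparent single-site Kd of a multivalent ligand in the trace-receptor
    limit.

    For independent classes with per-molecule site counts ``n_i`` and
    dissociation constants ``kd_i``, a trace receptor sees an apparent
    dissociation constant ``(sum_i n_i / kd_i)^-1`` against the ligand
    *molecule* concentration. Two identical sites halve the apparent Kd —
    an RT ln 2 energy gain, the ceiling for purely statistical avidity.
    """
    if len(site_kds) == 0:
        raise InvalidInputError("at least one site class is required")
    if sites_per_molecule is None:
        sites_per_molecule = [1.0] * len(site_kds)
    if len(sites_per_molecule) != len(site_kds):
        raise InvalidInputError("site_kds and sites_per_molecule lengths differ")
    total = 0.0
    for kd, n in zip(site_kds, sites_per_molecule):
        if not (kd > 0):
            raise InvalidInputError(f"kd must be > 0, got {kd}")
        if n < 0:
            raise InvalidInputError(f"sites_per_molecule must be >= 0, got {n}")
        total += n / kd
    if total == 0.0:
        raise InvalidInputError("no binding sites: apparent affinity undefined")
    return 1.0 / total
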