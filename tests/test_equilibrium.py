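"""Forward mass-action solvers: examples, mass conservation, avidity and
competition limits."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from supdep import (
    SiteClass,
    apparent_affinity_dilute_limit,
    dg_from_kd,
    solve_competition,
    solve_multisite,
    solve_single_site,
)
from supdep.errors import InvalidInputError

log_conc = st.floats(min_value=-9, max_value=-4)


class TestSingleSite:
    def test_no_ligand_means_no_binding(self):
        state = solve_single_site(1e-6, 0.0, 1e-7)
        assert state.fraction_receptor_bound_total == 0.0
        assert state.free_receptor == 1e-7

    def test_depleted_regime_reference_point(self):
        state = solve_single_site(kd=1e-6, l_total=2e-6, r_total=1e-7)
        assert state.bound_per_class[0] == pytest.approx(6.59e-8, rel=1e-3)
        assert state.fraction_receptor_bound_total == pytest.approx(0.659, abs=1e-3)

    def test_half_saturation_with_trace_receptor(self):
        state = solve_single_site(kd=1e-6, l_total=1e-6, r_total=1e-12)
        assert state.fraction_receptor_bound_total == pytest.approx(0.50, abs=1e-5)

    def test_rejects_negative_concentrations(self):
        with pytest.raises(InvalidInputError):
            solve_single_site(1e-6, -1e-7, 1e-7)

    @given(log_conc, log_conc, log_conc)
    def test_mass_action_and_conservation(self, lk, ll, lr):
        kd, l, r = 10.0**lk, 10.0**ll, 10.0**lr
        state = solve_single_site(kd, l, r)
        bound = state.bound_per_class[0]
        # receptor conservation
        assert state.free_receptor + bound == pytest.approx(r, rel=1e-9)
        # the root satisfies the mass-action law
        assert kd * bound == pytest.approx((l - bound) * (r - bound), rel=1e-9)
        assert 0.0 <= bound <= min(l, r)


class TestMultisite:
    def test_reduces_to_single_site(self):
        classes = [SiteClass(kd=3e-7, total_sites=5e-7)]
        multi = solve_multisite(classes, 2e-7)
        single = solve_single_site(3e-7, 5e-7, 2e-7)
        assert multi.free_receptor == pytest.approx(single.free_receptor, rel=1e-9)

    def test_splitting_a_class_changes_nothing(self):
        merged = solve_multisite([SiteClass(kd=1e-6, total_sites=2e-6)], 1e-7)
        split = solve_multisite(
            [SiteClass(kd=1e-6, total_sites=1e-6), SiteClass(kd=1e-6, total_sites=1e-6)],
            1e-7,
        )
        assert split.free_receptor == pytest.approx(merged.free_receptor, rel=1e-9)
        assert split.fraction_receptor_bound_total == pytest.approx(
            merged.fraction_receptor_bound_total, rel=1e-9
        )

    def test_dilute_two_class_closed_form(self):
        # trace receptor: fraction = (sum L/kd) / (1 + sum L/kd) = 0.2/1.2
        classes = [
            SiteClass(kd=1e-5, total_sites=1e-6),
            SiteClass(kd=1e-5, total_sites=1e-6),
        ]
        state = solve_multisite(classes, 1e-9)
        assert state.fraction_receptor_bound_total == pytest.approx(1.0 / 6.0, rel=1e-2)

    def test_rejects_empty_class_list(self):
        with pytest.raises(InvalidInputError):
            solve_multisite([], 1e-7)

    @given(
        st.lists(st.tuples(log_conc, log_conc), min_size=1, max_size=4),
        log_conc,
    )
    def test_conservation_for_every_class(self, class_params, lr):
        classes = [
            SiteClass(kd=10.0**lk, total_sites=10.0**ls) for lk, ls in class_params
        ]
        r = 10.0**lr
        state = solve_multisite(classes, r)
        assert state.free_receptor + sum(state.bound_per_class) == pytest.approx(
            r, rel=1e-9
        )
        for bound, c in zip(state.bound_per_class, classes):
            assert 0.0 <= bound <= min(c.total_sites, r) * (1 + 1e-12)
            # each class obeys mass action at the common free-receptor value
            free_sites = c.total_sites - bound
            assert c.kd * bound == pytest.approx(
                free_sites * state.free_receptor, rel=1e-9
            )

    def test_agrees_with_dilute_limit_when_receptor_is_trace(self):
        classes = [
            SiteClass(kd=1e-6, total_sites=1e-6),
            SiteClass(kd=1e-5, total_sites=1e-6),
        ]
        r = 1e-4 * min(c.total_sites for c in classes)
        state = solve_multisite(classes, r)
        kd_app = apparent_affinity_dilute_limit([1e-6, 1e-5])
        expected = 1e-6 / (kd_app + 1e-6)  # molecule concentration 1e-6
        assert state.fraction_receptor_bound_total == pytest.approx(expected, rel=1e-2)


class TestCompetition:
    def make(self, solid_sites=1e-6, comp_sites=1e-6, kd=1e-6):
        solid = SiteClass(kd=kd, total_sites=solid_sites, phase="solid")
        comp = SiteClass(kd=kd, total_sites=comp_sites, phase="soluble")
        return solid, comp

    def test_no_competitor_equals_single_site(self):
        solid, comp = self.make(comp_sites=0.0)
        state = solve_competition(solid, comp, 1e-9)
        single = solve_single_site(1e-6, 1e-6, 1e-9)
        assert state.fraction_receptor_bound_solid == pytest.approx(
            single.fraction_receptor_bound_total, rel=1e-9
        )

    def test_equal_competitor_dilute_closed_form(self):
        # c = L/kd = 1 for both: solid fraction = c / (1 + 2c) = 1/3
        solid, comp = self.make()
        state = solve_competition(solid, comp, 1e-9)
        assert state.fraction_receptor_bound_solid == pytest.approx(1.0 / 3.0, rel=1e-2)
        assert state.fraction_receptor_bound_solid <= state.fraction_receptor_bound_total

    def test_saturating_competitor_strips_the_resin(self):
        solid, comp = self.make(comp_sites=1e-2)
        state = solve_competition(solid, comp, 1e-9)
        assert state.fraction_receptor_bound_solid < 1e-3

    def test_solid_fraction_strictly_decreasing_in_competitor(self):
        fractions = []
        for comp_sites in [0.0, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3]:
            solid, comp = self.make(comp_sites=comp_sites)
            fractions.append(
                solve_competition(solid, comp, 1e-9).fraction_receptor_bound_solid
            )
        assert all(a > b for a, b in zip(fractions, fractions[1:]))

    def test_phase_preconditions(self):
        solid, comp = self.make()
        with pytest.raises(InvalidInputError):
            solve_competition(comp, comp, 1e-9)
        with pytest.raises(InvalidInputError):
            solve_competition(solid, solid, 1e-9)


class TestApparentAffinityDiluteLimit:
    def test_single_class_identity(self):
        assert apparent_affinity_dilute_limit([1e-6]) == pytest.approx(1e-6)

    def test_two_equal_sites_halve_the_kd(self):
        kd_app = apparent_affinity_dilute_limit([1e-6, 1e-6])
        assert kd_app == pytest.approx(5e-7, rel=1e-12)
        gain = dg_from_kd(kd_app) - dg_from_kd(1e-6)
        assert gain == pytest.approx(math.log(2) * 0.58255, abs=1e-3)  # RT ln 2

    def test_harmonic_combination(self):
        assert apparent_affinity_dilute_limit([1e-6, 1e-5]) == pytest.approx(
            9.0909e-7, rel=1e-4
        )

    def test_site_multiplicity(self):
        assert apparent_affinity_dilute_limit([1e-6], [2.0]) == pytest.approx(5e-7)
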