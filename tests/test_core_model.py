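"""Closed-form steady state, linear-system oracle and derived profiles."""

import numpy as np
import pytest
from hypothesis import given, settings

from csfmarkov import (
    DegenerateCompartmentError,
    InfeasibleRatesError,
    RateBoundsError,
    StageDistribution,
    TransitionRates,
    build_linear_system,
    compare_rates,
    compartment_profile,
    diff_fold_change,
    reference_rates,
    steady_state,
    validate_rates,
)

from conftest import interior_rates, valid_rates

# Stationary distributions computed independently by dense linear solve
# of the balance equations at the packaged reference rates.
CD8_CONTROLS_STEADY = np.array([0.8928535, 0.0010090, 0.1056418, 0.0004957])
NK_CONTROLS_STEADY = np.array([0.0634429, 0.0000764, 0.9364275, 0.0000532])


class TestValidateRates:
    def test_boundary_zero_rates_are_valid(self):
        r = TransitionRates(0.0, 0.0, 0.0, 0.0)
        assert validate_rates(r) is r

    def test_reference_rates_are_valid(self, cd8_controls):
        assert validate_rates(cd8_controls) is cd8_controls
        assert cd8_controls.beta2 == pytest.approx(0.197744)

    @pytest.mark.parametrize("name", ["alpha1", "alpha2", "beta1", "beta2"])
    @pytest.mark.parametrize("bad", [-0.01, 1.01, float("nan")])
    def test_out_of_bounds_rate_names_offender(self, name, bad):
        r = TransitionRates(**{**dict.fromkeys(
            ("alpha1", "alpha2", "beta1", "beta2"), 0.1), name: bad})
        with pytest.raises(RateBoundsError, match=name):
            validate_rates(r)

    def test_stage1_infeasibility(self):
        with pytest.raises(InfeasibleRatesError):
            validate_rates(TransitionRates(0.6, 0.1, 0.5, 0.1))


class TestSteadyState:
    def test_no_outflow_concentrates_in_stage_one(self):
        x = steady_state(TransitionRates(0.0, 0.0, 0.0, 0.0))
        assert np.allclose(x.as_array(), [1, 0, 0, 0])

    @pytest.mark.parametrize(
        "cell,group,expected",
        [("CD8", "controls", CD8_CONTROLS_STEADY), ("NK", "controls", NK_CONTROLS_STEADY)],
    )
    def test_reference_steady_states(self, cell, group, expected):
        x = steady_state(reference_rates(cell, group))
        assert np.allclose(x.as_array(), expected, atol=5e-8)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(valid_rates())
    def test_closed_form_matches_linear_solve_and_conserves(self, rates):
        closed = steady_state(rates).as_array()
        solved = build_linear_system(rates).solve()
        assert np.max(np.abs(closed - solved)) <= 1e-12
        assert abs(closed.sum() - 1.0) <= 1e-12
        assert np.all(closed >= -1e-15)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(interior_rates())
    def test_system_matrix_invertible_in_interior(self, rates):
        det = np.linalg.det(build_linear_system(rates).matrix)
        assert det != 0.0

    def test_printed_variant_conserves_but_differs(self, cd8_controls):
        alt = steady_state(cd8_controls, printed_variant=True).as_array()
        assert abs(alt.sum() - 1.0) <= 1e-12
        assert not np.allclose(alt, steady_state(cd8_controls).as_array())
        solved = build_linear_system(cd8_controls, printed_variant=True).solve()
        assert np.max(np.abs(alt - solved)) <= 1e-12

    def test_infeasible_rates_rejected(self):
        with pytest.raises(InfeasibleRatesError):
            steady_state(TransitionRates(0.6, 0.1, 0.5, 0.1))


class TestCompartmentProfile:
    def test_reference_profiles(self, cd8_controls, nk_controls):
        cd8 = compartment_profile(steady_state(cd8_controls))
        assert cd8.pb_diff_frac == pytest.approx(0.1058, abs=1e-4)
        assert cd8.csf_diff_frac == pytest.approx(0.3294, abs=1e-4)
        nk = compartment_profile(steady_state(nk_controls))
        assert nk.pb_naive_frac == pytest.approx(0.0635, abs=1e-4)
        assert nk.csf_naive_frac == pytest.approx(0.5894, abs=1e-3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(interior_rates())
    def test_fractions_and_masses_normalised(self, rates):
        p = compartment_profile(steady_state(rates))
        assert p.pb_naive_frac + p.pb_diff_frac == pytest.approx(1.0, abs=1e-12)
        assert p.csf_naive_frac + p.csf_diff_frac == pytest.approx(1.0, abs=1e-12)
        assert p.pb_mass + p.csf_mass == pytest.approx(1.0, abs=1e-12)

    def test_empty_csf_compartment_is_degenerate(self):
        with pytest.raises(DegenerateCompartmentError):
            compartment_profile(StageDistribution(1.0, 0.0, 0.0, 0.0))

    def test_monotone_in_differentiation_rates(self, cd8_controls):
        b2_grid = np.linspace(0.05, 0.95, 7)
        csf_diff = [
            compartment_profile(
                steady_state(cd8_controls.replace(beta2=b2))
            ).csf_diff_frac
            for b2 in b2_grid
        ]
        assert np.all(np.diff(csf_diff) > 0)
        b1_grid = np.linspace(0.05, 0.9, 7)
        pb_diff = [
            compartment_profile(
                steady_state(cd8_controls.replace(beta1=b1))
            ).pb_diff_frac
            for b1 in b1_grid
        ]
        assert np.all(np.diff(pb_diff) > 0)


class TestRateComparisons:
    def test_csf_vs_pb_differentiation_fold_change(self, cd8_controls, nk_controls):
        assert round(diff_fold_change(cd8_controls), 1) == 1.9
        assert diff_fold_change(nk_controls) == pytest.approx(0.2755, abs=1e-4)
        assert diff_fold_change(TransitionRates(0.1, 0.1, 0.3, 0.3)) == 1.0
        with pytest.raises(ZeroDivisionError):
            diff_fold_change(TransitionRates(0.1, 0.1, 0.0, 0.3))

    def test_treatment_fold_changes(self):
        naive = reference_rates("CD4", "RRMS_naive")
        assert np.allclose(compare_rates(naive, naive), 1.0)
        nat = compare_rates(reference_rates("CD4", "RRMS_NAT"), naive)
        assert nat[0] == pytest.approx(0.0908, abs=1e-4)  # migration suppressed
        alem = compare_rates(reference_rates("CD4", "RRMS_ALEM"), naive)
        assert alem[2] == pytest.approx(2.366, abs=1e-3)  # differentiation raised

    def test_zero_denominator_rejected(self, cd4_controls):
        with pytest.raises(ZeroDivisionError):
            compare_rates(cd4_controls, TransitionRates(0.0, 0.1, 0.1, 0.1))
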