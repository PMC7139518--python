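"""Least-squares calibration, identifiability and the equal-objective family."""

import numpy as np
import pytest
from hypothesis import given, settings

from csfmarkov import (
    CalibrationOptions,
    Cohort,
    CohortVectorSet,
    GeneratorConfig,
    InfeasibleRatesError,
    MissingDataError,
    PatientRecord,
    TransitionRates,
    assemble_stage_vectors,
    equivalent_rates,
    feasible_delta_interval,
    fit,
    generate_cohort,
    identifiable_combinations,
    objective,
    profile_fit,
    reference_rates,
    steady_state,
)

from conftest import interior_rates


def noise_free_vectors(rates, K=1):
    x = steady_state(rates).as_array()
    return CohortVectorSet(vectors=np.tile(x, (K, 1)), cell_type=rates.cell_type)


def make_record(pb_naive, csf_naive, pb_count=None, csf_count=None, pid="P1"):
    return PatientRecord(
        patient_id=pid, group="g", cell_type="CD8",
        pb_naive_pct=pb_naive, pb_diff_pct=100 - pb_naive,
        csf_naive_pct=csf_naive, csf_diff_pct=100 - csf_naive,
        pb_total_count=pb_count, csf_total_count=csf_count,
    )


class TestAssembleStageVectors:
    def test_count_weighted_proportional_arithmetic(self):
        cohort = Cohort(records=(make_record(90, 60, 9990, 10),))
        vs = assemble_stage_vectors(cohort, mode="count_weighted")
        assert np.allclose(vs.vectors[0], [0.8991, 0.0006, 0.0999, 0.0004])

    def test_fixed_weight(self):
        cohort = Cohort(records=(make_record(90, 60),))
        vs = assemble_stage_vectors(cohort, mode="fixed_weight", csf_weight=0.5)
        assert np.allclose(vs.vectors[0], [0.45, 0.30, 0.05, 0.20])

    def test_count_weighted_requires_counts(self):
        cohort = Cohort(records=(make_record(90, 60, pb_count=9990),))
        with pytest.raises(MissingDataError, match="csf_total_count"):
            assemble_stage_vectors(cohort, mode="count_weighted")

    def test_joint_mode_uses_four_stage_percentages(self):
        rec = PatientRecord(
            patient_id="J1", group="g", cell_type="CD8",
            pb_naive_pct=45.0, pb_diff_pct=5.0,
            csf_naive_pct=30.0, csf_diff_pct=20.0,
        )
        assert rec.is_joint
        vs = assemble_stage_vectors(Cohort(records=(rec,)), mode="joint")
        assert np.allclose(vs.vectors[0], [0.45, 0.30, 0.05, 0.20])
        with pytest.raises(ValueError, match="joint"):
            assemble_stage_vectors(Cohort(records=(rec,)), mode="count_weighted")

    def test_joint_mode_rejects_pairwise_records(self):
        with pytest.raises(ValueError, match="sum to 100"):
            assemble_stage_vectors(
                Cohort(records=(make_record(90, 60),)), mode="joint"
            )

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            assemble_stage_vectors(
                Cohort(records=(make_record(90, 60),)), mode="bogus"
            )


class TestObjective:
    def test_zero_at_own_steady_state(self, cd8_controls):
        assert objective(cd8_controls, noise_free_vectors(cd8_controls)) == 0.0

    def test_hand_expanded_distance(self, cd8_controls):
        vs = CohortVectorSet(vectors=np.array([[1.0, 0, 0, 0]]))
        assert objective(cd8_controls, vs) == pytest.approx(0.0226418, abs=1e-6)

    def test_mean_of_identical_terms(self, cd8_controls):
        vs1 = CohortVectorSet(vectors=np.array([[1.0, 0, 0, 0]]))
        vs5 = CohortVectorSet(vectors=np.tile([1.0, 0, 0, 0], (5, 1)))
        assert objective(cd8_controls, vs5) == objective(cd8_controls, vs1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortVectorSet(vectors=np.empty((0, 4)))


class TestFit:
    def test_noise_free_recovers_identifiable_combinations(self, cd8_controls):
        res = fit(noise_free_vectors(cd8_controls))
        assert res.objective <= 1e-12
        truth = identifiable_combinations(cd8_controls)
        assert np.allclose(res.combos, truth, atol=1e-6)
        assert res.converged and res.n_starts == 82
        assert res.family_width > 0

    def test_all_naive_blood_vector(self):
        vs = CohortVectorSet(vectors=np.array([[1.0, 0, 0, 0]]))
        res = fit(vs)
        assert res.rates.alpha1 == pytest.approx(0.0, abs=1e-8)
        assert res.rates.beta1 == pytest.approx(0.0, abs=1e-8)
        assert res.objective <= 1e-12

    def test_repeated_fits_are_bitwise_identical(self, cd8_controls):
        vs = noise_free_vectors(cd8_controls, K=3)
        a, b = fit(vs), fit(vs)
        assert a.rates == b.rates
        assert a.objective == b.objective
        assert a.combos == b.combos

    def test_fit_minimises_at_least_as_well_as_truth(self, cd4_controls):
        cohort = generate_cohort(cd4_controls, GeneratorConfig(n_patients=20, seed=7))
        vs = assemble_stage_vectors(cohort)
        res = fit(vs)
        assert res.objective <= objective(cd4_controls, vs) + 1e-15


class TestProfileFit:
    # Published differentiation rates (percent) recovered when the
    # migration rates are held at their generating values.
    CASES = [
        ("CD8", "controls", "beta2", 19.7744, 1e-3),
        ("CD8", "SuS", "beta1", 22.3179, 1e-3),
        ("CD8", "RRMS_naive", "beta1", 12.6372, 1e-3),
        ("CD8", "SuS", "beta2", 23.47, 5e-3),
        ("NK", "controls", "beta2", 25.7994, 1e-3),
    ]

    @pytest.mark.parametrize("cell,group,rate,expected_pct,tol", CASES)
    def test_recovers_published_differentiation_rates(
        self, cell, group, rate, expected_pct, tol
    ):
        truth = reference_rates(cell, group)
        res = profile_fit(
            noise_free_vectors(truth),
            fixed={"alpha1": truth.alpha1, "alpha2": truth.alpha2},
        )
        assert 100 * getattr(res.rates, rate) == pytest.approx(expected_pct, abs=tol)
        assert res.family_width == 0.0

    def test_all_rates_fixed_skips_search(self, cd8_controls):
        vs = noise_free_vectors(cd8_controls)
        res = profile_fit(
            vs,
            fixed={n: getattr(cd8_controls, n)
                   for n in ("alpha1", "alpha2", "beta1", "beta2")},
        )
        assert res.n_starts == 0
        assert res.objective == objective(cd8_controls, vs)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(interior_rates())
    def test_matches_closed_form_oracle(self, truth):
        """With migrations fixed, beta1 = x3(1+alpha2) and
        beta2 = alpha1/x2 - 1 are the unique solutions."""
        x = steady_state(truth).as_array()
        b1_oracle = x[2] * (1 + truth.alpha2)
        b2_oracle = truth.alpha1 / x[1] - 1
        res = profile_fit(
            noise_free_vectors(truth),
            fixed={"alpha1": truth.alpha1, "alpha2": truth.alpha2},
        )
        assert res.rates.beta1 == pytest.approx(b1_oracle, abs=1e-6)
        assert res.rates.beta2 == pytest.approx(b2_oracle, abs=1e-4)


class TestIdentifiability:
    def test_zero_rates_give_zero_combos(self):
        assert identifiable_combinations(TransitionRates(0, 0, 0, 0)) == (0, 0, 0)

    def test_reference_combos(self, cd8_controls):
        s1, s2, s3 = identifiable_combinations(cd8_controls)
        assert s1 == pytest.approx(0.1071465, abs=1e-7)
        assert s2 == pytest.approx(0.0010090, abs=1e-7)
        assert s3 == pytest.approx(0.1056418, abs=1e-7)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(interior_rates())
    def test_combos_equal_steady_state_coordinates(self, rates):
        s1, s2, s3 = identifiable_combinations(rates)
        x = steady_state(rates).as_array()
        assert s1 == pytest.approx(1 - x[0], abs=1e-12)
        assert s2 == pytest.approx(x[1], abs=1e-12)
        assert s3 == pytest.approx(x[2], abs=1e-12)


class TestEquivalentRates:
    def test_zero_delta_is_identity(self, cd4_controls):
        assert equivalent_rates(cd4_controls, 0.0) is cd4_controls

    def test_constructed_family_member(self, cd4_controls):
        alt = equivalent_rates(cd4_controls, 2e-5)
        assert alt.alpha1 == pytest.approx(0.00113389, abs=1e-9)
        assert alt.beta1 == pytest.approx(0.0635874, abs=1e-9)
        assert alt.alpha2 == pytest.approx(0.000596, abs=2e-6)
        assert alt.beta2 == pytest.approx(0.068303, abs=1e-5)
        dx = steady_state(alt).as_array() - steady_state(cd4_controls).as_array()
        assert np.max(np.abs(dx)) <= 1e-12

    def test_delta_beyond_family_is_infeasible(self, cd4_controls):
        lo, hi = feasible_delta_interval(cd4_controls)
        assert hi == pytest.approx(5.79e-5, abs=1e-7)
        with pytest.raises(InfeasibleRatesError):
            equivalent_rates(cd4_controls, 1e-3)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(interior_rates())
    def test_family_preserves_objective(self, rates):
        vs = CohortVectorSet(vectors=np.array([[0.7, 0.05, 0.2, 0.05]]))
        lo, hi = feasible_delta_interval(rates)
        for frac in (0.25, 0.75):
            delta = lo + frac * (hi - lo)
            alt = equivalent_rates(rates, delta)
            assert objective(alt, vs) == pytest.approx(
                objective(rates, vs), abs=1e-12
            )


class TestConsistency:
    def test_combo_error_shrinks_with_event_counts(self, cd8_controls):
        """Quadrupling the flow-cytometry event counts roughly halves the
        calibration error of the identifiable combinations."""
        truth = np.array(identifiable_combinations(cd8_controls))
        opts = CalibrationOptions(multistart_grid=1)

        def rms_error(scale, seeds):
            errs = []
            for seed in seeds:
                cfg = GeneratorConfig(
                    n_patients=30, n_pb_events=10_000 * scale,
                    n_csf_events=200 * scale, seed=seed,
                )
                vs = assemble_stage_vectors(generate_cohort(cd8_controls, cfg))
                res = fit(vs, opts)
                errs.append(np.array(res.combos) - truth)
            return np.sqrt(np.mean(np.square(errs)))

        seeds = range(100, 108)
        ratio = rms_error(4, seeds) / rms_error(1, seeds)
        assert 0.25 <= ratio <= 0.8
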