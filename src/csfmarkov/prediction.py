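"""CSF profile prediction from peripheral-blood data only.

Lumbar puncture is invasive and often unavailable, whereas blood is easy
to sample.  Given cohort-calibrated rates, a new patient's CSF
naive/differentiated split is predicted from their blood split alone:
the patient's PB differentiation rate ``beta1`` is inferred so that the
model's PB profile matches the measurement exactly (the only rate a PB
measurement can pin down), the remaining rates stay at cohort values,
and the model's stationary CSF profile is read off.

Uncertainty from calibrating on a finite training cohort is quantified
by a percentile bootstrap: the cohort is resampled with replacement, the
rates refitted and the prediction repeated, yielding a 95% range per
predicted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calibration import (
    CalibrationOptions,
    CohortVectorSet,
    assemble_stage_vectors,
    fit,
)
from .cohort import Cohort
from .core import compartment_profile, steady_state
from .exceptions import InfeasibleRatesError, NonConvergenceError
from .rates import TransitionRates, validate_rates

__all__ = [
    "PredictionResult",
    "infer_patient_beta1",
    "predict_csf",
    "bootstrap_prediction",
]


@dataclass(frozen=True)
class PredictionResult:
    """Predicted CSF naive/differentiated fractions for one patient.

    ``range_low`` / ``range_high`` are optional length-2 arrays of
    bootstrap 2.5th/97.5th percentiles over (csf_naive_frac,
    csf_diff_frac); ``n_failures`` counts bootstrap resamples whose refit
    did not converge and was skipped.
    """

    csf_naive_frac: float
    csf_diff_frac: float
    patient_beta1: float
    range_low: Optional[np.ndarray] = None
    range_high: Optional[np.ndarray] = None
    n_failures: int = 0


def infer_patient_beta1(
    pb_naive_frac: float, cohort_rates: TransitionRates
) -> float:
    """PB differentiation rate reproducing a patient's blood profile.

    With ``alpha1``, ``alpha2``, ``beta2`` held at cohort values, solving
    the stationary PB split for ``beta1`` gives::

        beta1 = (1 - p)(1 - alpha1) / [ p/(1 + alpha2) + (1 - p) ]

    where ``p`` is the patient's naive fraction within PB.  ``p = 1``
    yields ``beta1 = 0`` (an all-naive blood pool implies no
    differentiation); ``p = 0`` yields ``beta1 = 1 - alpha1``.
    """
    validate_rates(cohort_rates)
    p = float(pb_naive_frac)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"pb_naive_frac={p!r} outside [0, 1]")
    a1, a2 = cohort_rates.alpha1, cohort_rates.alpha2
    beta1 = (1.0 - p) * (1.0 - a1) / (p / (1.0 + a2) + (1.0 - p))
    if not -1e-12 <= beta1 <= 1.0 - a1 + 1e-12:
        raise InfeasibleRatesError(
            f"inferred beta1={beta1:.6g} outside [0, 1 - alpha1]"
        )
    return float(np.clip(beta1, 0.0, 1.0 - a1))


def predict_csf(
    pb_profile: Sequence[float], cohort_rates: TransitionRates
) -> PredictionResult:
    """Predict the CSF naive/differentiated split from a PB split.

    ``pb_profile`` is ``(pb_naive_frac, pb_diff_frac)`` and must sum
    to 1.  The patient-specific ``beta1`` is inferred, substituted into
    the steady state with cohort ``alpha1, alpha2, beta2``, and the CSF
    pair renormalised within the CSF compartment.
    """
    pb_naive, pb_diff = (float(v) for v in pb_profile)
    if abs(pb_naive + pb_diff - 1.0) > 1e-9:
        raise ValueError(
            f"pb profile ({pb_naive}, {pb_diff}) does not sum to 1"
        )
    beta1 = infer_patient_beta1(pb_naive, cohort_rates)
    patient_rates = cohort_rates.replace(beta1=beta1)
    profile = compartment_profile(steady_state(patient_rates))
    return PredictionResult(
        csf_naive_frac=profile.csf_naive_frac,
        csf_diff_frac=profile.csf_diff_frac,
        patient_beta1=beta1,
    )


def bootstrap_prediction(
    cohort: Cohort,
    new_pb_profiles: Sequence[Sequence[float]],
    B: int = 1000,
    seed: int = 0,
    assembly_mode: str = "count_weighted",
    csf_weight: float = 0.001,
    options: Optional[CalibrationOptions] = None,
    resample: bool = True,
) -> list[PredictionResult]:
    """Point predictions with bootstrap 95% ranges.

    The training cohort is resampled with replacement ``B`` times; rates
    are refitted on each resample (warm-started from the full-cohort fit
    and the feasible-set centre) and each new patient's CSF pair is
    re-predicted.  Point estimates come from the full-cohort fit; ranges
    are the 2.5th-97.5th percentiles across resamples.  Fully
    reproducible given ``seed``.  With ``resample=False`` every replicate
    uses the full cohort, so ranges collapse onto the point estimate.

    Resamples whose refit fails are skipped and counted in
    ``n_failures``; more than 50% failures raises
    :class:`NonConvergenceError`.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    vectors = assemble_stage_vectors(cohort, mode=assembly_mode, csf_weight=csf_weight)
    full_fit = fit(vectors, options)
    point = [predict_csf(p, full_fit.rates) for p in new_pb_profiles]

    boot_options = CalibrationOptions(
        tolerance=(options.tolerance if options else 1e-16),
        multistart_grid=1,
        extra_starts=(tuple(full_fit.rates.as_array()),),
    )
    rng = np.random.default_rng(seed)
    K = len(vectors)
    samples = np.full((B, len(point), 2), np.nan)
    failures = 0
    for b in range(B):
        idx = rng.integers(0, K, size=K) if resample else np.arange(K)
        sub = CohortVectorSet(
            vectors=vectors.vectors[idx],
            cell_type=vectors.cell_type,
            assembly_mode=vectors.assembly_mode,
        )
        try:
            refit = fit(sub, boot_options)
            for j, p in enumerate(new_pb_profiles):
                pred = predict_csf(p, refit.rates)
                samples[b, j] = (pred.csf_naive_frac, pred.csf_diff_frac)
        except (NonConvergenceError, InfeasibleRatesError):
            failures += 1
    if failures > B / 2:
        raise NonConvergenceError(
            f"{failures}/{B} bootstrap refits failed to converge"
        )

    ok = ~np.isnan(samples[:, 0, 0])
    lo = np.percentile(samples[ok], 2.5, axis=0)
    hi = np.percentile(samples[ok], 97.5, axis=0)
    return [
        PredictionResult(
            csf_naive_frac=pr.csf_naive_frac,
            csf_diff_frac=pr.csf_diff_frac,
            patient_beta1=pr.patient_beta1,
            range_low=np.minimum(lo[j], [pr.csf_naive_frac, pr.csf_diff_frac]),
            range_high=np.maximum(hi[j], [pr.csf_naive_frac, pr.csf_diff_frac]),
            n_failures=failures,
        )
        for j, pr in enumerate(point)
    ]
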