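"""Model/Results interface for the four-stage trafficking model.

`MarkovStageModel` holds the data (per-patient stage vectors, optionally
the cohort they came from); `fit` returns a `MarkovStageResults` carrying
the estimated rates, the identifiable combinations, degeneracy
diagnostics and prediction methods.

Example
-------
>>> from csfmarkov import MarkovStageModel, generate_cohort, GeneratorConfig
>>> from csfmarkov import reference_rates
>>> cohort = generate_cohort(reference_rates("CD8", "controls"),
...                          GeneratorConfig(n_patients=75, seed=1))
>>> res = MarkovStageModel.from_cohort(cohort).fit()
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .calibration import (
    CalibrationOptions,
    CalibrationResult,
    CohortVectorSet,
    assemble_stage_vectors,
    fit as _fit,
    objective as _objective,
)
from .cohort import Cohort
from .core import (
    CompartmentProfile,
    StageDistribution,
    compartment_profile,
    compare_rates,
    steady_state,
)
from .prediction import PredictionResult, bootstrap_prediction, predict_csf
from .rates import RATE_NAMES, TransitionRates

__all__ = ["MarkovStageModel", "MarkovStageResults"]


class MarkovStageModel:
    """Four-stage steady-state trafficking model bound to cohort data.

    Parameters
    ----------
    vectors : CohortVectorSet or (K, 4) array_like
        Per-patient stage probability vectors.
    cohort : Cohort, optional
        The source records; required for bootstrap prediction.
    """

    def __init__(self, vectors, cohort: Optional[Cohort] = None, cell_type: str = ""):
        if not isinstance(vectors, CohortVectorSet):
            vectors = CohortVectorSet(
                vectors=np.asarray(vectors, dtype=float), cell_type=cell_type
            )
        self.vectors = vectors
        self.cohort = cohort
        self.assembly_mode = vectors.assembly_mode
        self.csf_weight: float = 0.001

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        mode: str = "count_weighted",
        csf_weight: float = 0.001,
    ) -> "MarkovStageModel":
        """Build the model from patient records, assembling stage vectors."""
        vectors = assemble_stage_vectors(cohort, mode=mode, csf_weight=csf_weight)
        model = cls(vectors, cohort=cohort)
        model.csf_weight = csf_weight
        return model

    @property
    def nobs(self) -> int:
        return len(self.vectors)

    def loss(self, rates: TransitionRates) -> float:
        """Mean squared deviation of the model steady state from the data."""
        return _objective(rates, self.vectors)

    def fit(
        self,
        tolerance: float = 1e-16,
        multistart_grid: int = 3,
        fixed: Optional[dict] = None,
        **kwargs,
    ) -> "MarkovStageResults":
        """Calibrate the rates by constrained least squares.

        ``fixed`` holds named rates at given values (profile
        calibration); remaining keyword arguments are passed through to
        :class:`~csfmarkov.calibration.CalibrationOptions`.
        """
        options = CalibrationOptions(
            tolerance=tolerance, multistart_grid=multistart_grid, fixed=fixed, **kwargs
        )
        return MarkovStageResults(self, _fit(self.vectors, options), options)


class MarkovStageResults:
    """Fit results: estimated rates, diagnostics, prediction."""

    def __init__(
        self,
        model: MarkovStageModel,
        calibration: CalibrationResult,
        options: CalibrationOptions,
    ):
        self.model = model
        self.calibration = calibration
        self.options = options

    # -- estimates ----------------------------------------------------
    @property
    def rates(self) -> TransitionRates:
        return self.calibration.rates

    @property
    def params(self) -> np.ndarray:
        """Fitted rates as fractions, ordered (alpha1, alpha2, beta1, beta2)."""
        return self.calibration.rates.as_array()

    @property
    def objective(self) -> float:
        return self.calibration.objective

    @property
    def identifiable_combinations(self) -> tuple:
        return self.calibration.combos

    @property
    def family_width(self) -> float:
        return self.calibration.family_width

    @property
    def converged(self) -> bool:
        return self.calibration.converged

    # -- derived quantities -------------------------------------------
    @property
    def steady_state(self) -> StageDistribution:
        return steady_state(self.rates)

    @property
    def compartment_profile(self) -> CompartmentProfile:
        return compartment_profile(self.steady_state)

    def compare(self, other) -> np.ndarray:
        """Per-rate fold changes of these rates over another fit/rates."""
        other_rates = other.rates if isinstance(other, MarkovStageResults) else other
        return compare_rates(self.rates, other_rates)

    # -- prediction ----------------------------------------------------
    def predict_csf(
        self,
        pb_profiles,
        bootstrap: int = 0,
        seed: int = 0,
    ) -> "PredictionResult | list[PredictionResult]":
        """Predict CSF naive/differentiated splits from PB splits.

        ``pb_profiles`` is one ``(pb_naive_frac, pb_diff_frac)`` pair or a
        sequence of them.  With ``bootstrap=B > 0`` the training cohort
        (required on the model) is resampled B times to attach 95%
        ranges.
        """
        single = np.ndim(pb_profiles[0]) == 0
        profiles: Sequence = [pb_profiles] if single else list(pb_profiles)
        if bootstrap > 0:
            if self.model.cohort is None:
                raise ValueError(
                    "bootstrap prediction requires a model built from a cohort"
                )
            out = bootstrap_prediction(
                self.model.cohort,
                profiles,
                B=bootstrap,
                seed=seed,
                assembly_mode=self.model.assembly_mode or "count_weighted",
                csf_weight=self.model.csf_weight,
                options=self.options,
            )
        else:
            out = [predict_csf(p, self.rates) for p in profiles]
        return out[0] if single else out

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        c = self.calibration
        x = self.steady_state.as_array()
        prof = self.compartment_profile
        lines = [
            "Four-stage blood/CSF trafficking model — least-squares calibration",
            "=" * 68,
            f"cell type: {self.model.vectors.cell_type or '-':<16}"
            f"patients (K): {self.model.nobs}",
            f"assembly:  {self.model.assembly_mode or 'direct':<16}"
            f"starts: {c.n_starts}   converged: {c.converged}",
            f"objective (mean squared deviation): {c.objective:.6e}",
            "-" * 68,
            "rate        estimate (%)   identifiable combination",
            f"alpha1      {100 * self.params[0]:>12.6g}   s1 = alpha1+beta1      = {c.combos[0]:.6g}",
            f"alpha2      {100 * self.params[1]:>12.6g}   s2 = alpha1/(1+beta2)  = {c.combos[1]:.6g}",
            f"beta1       {100 * self.params[2]:>12.6g}   s3 = beta1/(1+alpha2)  = {c.combos[2]:.6g}",
            f"beta2       {100 * self.params[3]:>12.6g}",
            "-" * 68,
            f"stationary stages (x1..x4): {x[0]:.5f} {x[1]:.5f} {x[2]:.5f} {x[3]:.5f}",
            f"PB naive/diff: {100 * prof.pb_naive_frac:.2f}/{100 * prof.pb_diff_frac:.2f} %   "
            f"CSF naive/diff: {100 * prof.csf_naive_frac:.2f}/{100 * prof.csf_diff_frac:.2f} %",
            f"equal-objective family width (delta interval): {c.family_width:.3g}",
            "=" * 68,
            "Raw rates are identified only up to the (s1, s2, s3) manifold;",
            "interpret individual rates together with the family width.",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        r = {n: round(100 * v, 4) for n, v in zip(RATE_NAMES, self.params)}
        return f"<MarkovStageResults rates(%)={r} objective={self.objective:.3e}>"
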