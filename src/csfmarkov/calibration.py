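"""Cohort calibration of transition rates by constrained least squares.

Given K per-patient stage vectors ``X_k`` (probabilities over the four
stages), the rates are estimated by minimising the unweighted mean squared
deviation::

    (1/K) * sum_k || X(alpha, beta) - X_k ||^2

subject to ``0 <= alpha, beta <= 1`` and the feasibility constraint
``alpha1 + beta1 <= 1``, where ``X(alpha, beta)`` is the model's
stationary stage distribution.

Structural identifiability
--------------------------
The stationary distribution determines exactly three functions of the
four rates::

    s1 = alpha1 + beta1          (= 1 - x1)
    s2 = alpha1 / (1 + beta2)    (= x2)
    s3 = beta1 / (1 + alpha2)    (= x3)

so a one-parameter family of rate vectors shares any given steady state:
raw rates are *not* identifiable from steady-state data alone, and only
recovery of ``(s1, s2, s3)`` can be asserted.  :func:`equivalent_rates`
constructs explicit members of the family, :func:`feasible_delta_interval`
bounds it, and :class:`CalibrationResult` reports its width instead of
hiding the degeneracy.  Well-posed recovery of individual differentiation
rates is available through :func:`profile_fit` with the migration rates
held fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .cohort import Cohort
from .exceptions import (
    InfeasibleRatesError,
    MissingDataError,
    NonConvergenceError,
)
from .rates import RATE_NAMES, TransitionRates, validate_rates

__all__ = [
    "CohortVectorSet",
    "CalibrationOptions",
    "CalibrationResult",
    "assemble_stage_vectors",
    "objective",
    "fit",
    "profile_fit",
    "identifiable_combinations",
    "equivalent_rates",
    "feasible_delta_interval",
]

_EPS = np.finfo(float).eps
# Centroid of the feasible set: (alpha1, beta1) range over the triangle
# {a1 + b1 <= 1} (centroid 1/3, 1/3); alpha2, beta2 over [0, 1].
_FEASIBLE_CENTER = np.array([1.0 / 3.0, 0.5, 1.0 / 3.0, 0.5])


@dataclass(frozen=True)
class CohortVectorSet:
    """K per-patient four-stage probability vectors for one lineage."""

    vectors: np.ndarray
    cell_type: str = ""
    assembly_mode: str = ""

    def __post_init__(self):
        arr = np.asarray(self.vectors, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise ValueError(f"vectors must be (K, 4) with K >= 1, got {arr.shape}")
        if np.any(arr < -1e-12):
            raise ValueError("stage vectors must be nonnegative")
        sums = arr.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"stage vector {bad[0]} sums to {sums[bad[0]]!r}, not 1"
            )
        object.__setattr__(self, "vectors", arr)

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def mean_vector(self) -> np.ndarray:
        return self.vectors.mean(axis=0)


@dataclass(frozen=True)
class CalibrationOptions:
    """Optimiser settings.

    ``tolerance`` is the requested objective-decrease threshold; values
    below machine epsilon are clipped to it (the tightest achievable).
    ``multistart_grid`` is the number of deterministic start values per
    free rate (grid over [0.1, 0.9], e.g. 3 -> {0.1, 0.5, 0.9}); the
    centre of the feasible set is always added as a start.  ``fixed``
    holds a subset of rate names at given values (profile calibration).
    ``extra_starts`` adds warm starts (full 4-vectors of fractions).
    """

    tolerance: float = 1e-16
    multistart_grid: int = 3
    fixed: Optional[dict] = None
    bounds: tuple = (0.0, 1.0)
    extra_starts: tuple = ()
    maxiter: int = 300

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.multistart_grid < 1:
            raise ValueError("multistart_grid must be >= 1")
        if self.fixed:
            for name in self.fixed:
                if name not in RATE_NAMES:
                    raise ValueError(f"unknown rate name {name!r} in fixed")

    @property
    def ftol(self) -> float:
        return max(self.tolerance, _EPS)


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted rates with diagnostics.

    ``combos`` are the identifiable combinations ``(s1, s2, s3)`` of the
    fitted rates; ``family_width`` is the length of the feasible interval
    of the equal-objective solution family through the fitted point (0
    means the fit is pinned, e.g. by profile constraints).
    """

    rates: TransitionRates
    objective: float
    combos: tuple
    converged: bool
    n_starts: int
    family_width: float
    diagnostics: tuple = field(default=(), repr=False)


def assemble_stage_vectors(
    cohort: Cohort, mode: str = "count_weighted", csf_weight: float = 0.001
) -> CohortVectorSet:
    """Combine per-compartment percentages into four-stage vectors.

    Modes
    -----
    ``"count_weighted"``
        Compartment masses proportional to the recorded total cell
        counts (requires both counts on every record).
    ``"fixed_weight"``
        CSF mass fixed at ``csf_weight`` for every patient.  The default
        0.001 is a stated assumption reflecting that the CSF holds a tiny
        fraction of the body's lymphocytes, not an inference from data.
    ``"joint"``
        The record's four percentages already form a joint distribution
        summing to 100; they are used directly.
    """
    vectors = []
    for i, rec in enumerate(cohort):
        if rec.is_joint and mode != "joint":
            raise ValueError(
                f"record {i} ({rec.patient_id}) is jointly normalised; "
                "use assembly mode 'joint'"
            )
        pb = np.array([rec.pb_naive_pct, rec.pb_diff_pct]) / 100.0
        csf = np.array([rec.csf_naive_pct, rec.csf_diff_pct]) / 100.0
        if mode == "count_weighted":
            if rec.pb_total_count is None or rec.csf_total_count is None:
                raise MissingDataError(
                    f"record {i} ({rec.patient_id}): count_weighted assembly "
                    "requires pb_total_count and csf_total_count; use "
                    "fixed_weight if counts are unavailable"
                )
            total = rec.pb_total_count + rec.csf_total_count
            if total <= 0:
                raise MissingDataError(
                    f"record {i} ({rec.patient_id}): zero total cell count"
                )
            w_csf = rec.csf_total_count / total
        elif mode == "fixed_weight":
            if not 0.0 < csf_weight < 1.0:
                raise ValueError("csf_weight must lie strictly in (0, 1)")
            w_csf = csf_weight
        elif mode == "joint":
            four = np.array(
                [rec.pb_naive_pct, rec.csf_naive_pct, rec.pb_diff_pct, rec.csf_diff_pct]
            )
            if abs(four.sum() - 100.0) > 0.5:
                raise ValueError(
                    f"record {i} ({rec.patient_id}): joint assembly requires "
                    f"the four percentages to sum to 100, got {four.sum():.4g}"
                )
            vectors.append(four / four.sum())
            continue
        else:
            raise ValueError(f"unknown assembly mode {mode!r}")
        w_pb = 1.0 - w_csf
        vectors.append(
            np.array([w_pb * pb[0], w_csf * csf[0], w_pb * pb[1], w_csf * csf[1]])
        )
    return CohortVectorSet(
        vectors=np.array(vectors), cell_type=cohort.cell_type, assembly_mode=mode
    )


def _steady_vector(theta: np.ndarray) -> np.ndarray:
    a1, a2, b1, b2 = theta
    x2 = a1 / (1.0 + b2)
    x3 = b1 / (1.0 + a2)
    return np.array([1.0 - a1 - b1, x2, x3, b2 * x2 + a2 * x3])


def _steady_jacobian(theta: np.ndarray) -> np.ndarray:
    """d x_i / d theta_j with theta = (alpha1, alpha2, beta1, beta2)."""
    a1, a2, b1, b2 = theta
    db2 = 1.0 + b2
    da2 = 1.0 + a2
    return np.array(
        [
            [-1.0, 0.0, -1.0, 0.0],
            [1.0 / db2, 0.0, 0.0, -a1 / db2**2],
            [0.0, -b1 / da2**2, 1.0 / da2, 0.0],
            [b2 / db2, b1 / da2**2, a2 / da2, a1 / db2**2],
        ]
    )


def objective(rates: TransitionRates, vectors: CohortVectorSet) -> float:
    """Mean squared deviation between the model steady state and the data."""
    validate_rates(rates)
    diffs = _steady_vector(rates.as_array())[None, :] - vectors.vectors
    return float(np.mean(np.sum(diffs**2, axis=1)))


# The least-squares solver works in transformed coordinates that turn the
# feasibility constraint alpha1 + beta1 <= 1 into plain box bounds:
# when both alpha1 and beta1 are free, the third coordinate is
# t = beta1 / (1 - alpha1) in [0, 1]; when at most one of them is free,
# its own bound is tightened instead.


def _transform(z, free_idx, fixed_full, reparam):
    """Solver coordinates -> full rate vector theta."""
    theta = fixed_full.copy()
    theta[free_idx] = z
    if reparam:
        theta[2] = theta[2] * (1.0 - theta[0])  # t -> beta1
    return theta


def _inverse_transform(theta, reparam):
    z = theta.copy()
    if reparam:
        z[2] = 0.0 if theta[0] >= 1.0 else theta[2] / (1.0 - theta[0])
    return z


def _chain_jacobian(theta_jac, z_full, free_idx, reparam):
    """d x / d z from d x / d theta (chain rule through the reparam)."""
    if reparam:
        a1, t = z_full[0], z_full[2]
        # beta1 = t (1 - alpha1): d beta1/d alpha1 = -t, d beta1/d t = 1 - alpha1
        theta_jac = theta_jac.copy()
        theta_jac[:, 0] = theta_jac[:, 0] - t * theta_jac[:, 2]
        theta_jac[:, 2] = (1.0 - a1) * theta_jac[:, 2]
    return theta_jac[:, free_idx]


def _start_points(options: CalibrationOptions, free: np.ndarray, fixed_full: np.ndarray):
    """Deterministic multistart grid over the free rates, feasibility-clipped."""
    m = options.multistart_grid
    values = np.linspace(0.1, 0.9, m) if m > 1 else np.array([0.5])
    starts = []
    for combo in itertools.product(values, repeat=int(free.sum())):
        theta = fixed_full.copy()
        theta[free] = combo
        starts.append(theta)
    center = fixed_full.copy()
    center[free] = _FEASIBLE_CENTER[free]
    starts.append(center)
    for extra in options.extra_starts:
        theta = fixed_full.copy()
        theta[free] = np.asarray(extra, dtype=float)[free]
        starts.append(theta)
    clipped = []
    for theta in starts:
        s = theta[0] + theta[2]
        if s > 1.0:  # project onto the feasible triangle
            theta = theta.copy()
            theta[[0, 2]] *= (1.0 - 1e-9) / s
        clipped.append(theta)
    return clipped


def fit(
    vectors: CohortVectorSet, options: Optional[CalibrationOptions] = None
) -> CalibrationResult:
    """Constrained least-squares estimate of the transition rates.

    Runs a bounded local least-squares solve (trust-region reflective
    with analytic Jacobian; the constraint ``alpha1 + beta1 <= 1`` is
    made a box bound by the substitution ``beta1 = t (1 - alpha1)``)
    from every point of a deterministic multistart grid plus the
    feasible-set centre; the best objective wins, with ties broken by
    the smallest L2 norm of the rate vector and then by grid order, so
    repeated calls are bitwise identical.

    Because the model is structurally rank-3, the reported ``combos``
    ``(s1, s2, s3)`` are the recoverable quantities; ``family_width``
    quantifies the remaining equal-objective freedom in the raw rates.

    Raises
    ------
    NonConvergenceError
        If the optimiser fails (raises, or returns a non-finite
        objective) at every start; carries per-start diagnostics.
    """
    if options is None:
        options = CalibrationOptions()
    fixed = options.fixed or {}
    free = np.array([name not in fixed for name in RATE_NAMES])
    fixed_full = np.zeros(4)
    for j, name in enumerate(RATE_NAMES):
        if name in fixed:
            fixed_full[j] = float(fixed[name])
            if not 0.0 <= fixed_full[j] <= 1.0:
                raise InfeasibleRatesError(f"fixed {name}={fixed[name]} outside [0, 1]")

    mean_vec = vectors.mean_vector
    spread = float(np.mean(np.sum((vectors.vectors - mean_vec) ** 2, axis=1)))

    if not free.any():
        rates = TransitionRates.from_array(fixed_full, cell_type=vectors.cell_type)
        return CalibrationResult(
            rates=rates,
            objective=objective(rates, vectors),
            combos=identifiable_combinations(rates),
            converged=True,
            n_starts=0,
            family_width=0.0,
        )

    free_idx = np.where(free)[0]
    reparam = bool(free[0] and free[2])

    lo, hi = options.bounds
    lb = np.full(free_idx.size, lo)
    ub = np.full(free_idx.size, hi)
    if not reparam:  # tighten the free member of the (alpha1, beta1) pair
        for pos, j in enumerate(free_idx):
            if j == 0 and not free[2]:
                ub[pos] = min(ub[pos], 1.0 - fixed_full[2])
            if j == 2 and not free[0]:
                ub[pos] = min(ub[pos], 1.0 - fixed_full[0])

    def residuals(z):
        return _steady_vector(_transform(z, free_idx, fixed_full, reparam)) - mean_vec

    def jacobian(z):
        theta = _transform(z, free_idx, fixed_full, reparam)
        z_full = _inverse_transform(theta, reparam)
        return _chain_jacobian(_steady_jacobian(theta), z_full, free_idx, reparam)

    candidates = []
    diagnostics = []
    starts = _start_points(options, free, fixed_full)
    for idx, theta0 in enumerate(starts):
        z0 = np.clip(_inverse_transform(theta0, reparam)[free_idx], lb, ub)
        try:
            res = least_squares(
                residuals,
                z0,
                jac=jacobian,
                bounds=(lb, ub),
                method="trf",
                ftol=options.ftol,
                xtol=options.ftol,
                gtol=options.ftol,
                max_nfev=options.maxiter,
            )
        except Exception as exc:  # solver blow-up at this start
            diagnostics.append({"start": idx, "error": repr(exc)})
            continue
        obj = float(res.fun @ res.fun) + spread
        diagnostics.append(
            {
                "start": idx,
                "status": int(res.status),
                "message": res.message,
                "objective": obj,
                "success": bool(res.status > 0),
            }
        )
        if np.isfinite(obj):
            theta = _transform(np.clip(res.x, lb, ub), free_idx, fixed_full, reparam)
            theta = np.clip(theta, 0.0, 1.0)
            candidates.append(
                (obj, float(np.linalg.norm(theta)), idx, theta, bool(res.status > 0))
            )

    if not candidates:
        raise NonConvergenceError(
            "optimisation failed at every start point", diagnostics=diagnostics
        )

    best_obj = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_obj + 1e-12]
    tied.sort(key=lambda c: (c[1], c[2]))
    obj_sel, _, _, theta_sel, success_sel = tied[0]

    rates = TransitionRates.from_array(theta_sel, cell_type=vectors.cell_type)
    validate_rates(rates)
    if free.all():
        d_lo, d_hi = feasible_delta_interval(rates)
        family_width = max(d_hi - d_lo, 0.0)
    else:
        family_width = 0.0
    return CalibrationResult(
        rates=rates,
        objective=objective(rates, vectors),
        combos=identifiable_combinations(rates),
        converged=success_sel,
        n_starts=len(starts),
        family_width=family_width,
        diagnostics=tuple(diagnostics),
    )


def profile_fit(
    vectors: CohortVectorSet,
    fixed: dict,
    options: Optional[CalibrationOptions] = None,
) -> CalibrationResult:
    """Calibrate over a subset of rates with the complement held fixed.

    Fixing both migration rates renders the reduced problem well-posed:
    the differentiation rates are then uniquely determined by the data
    (closed forms ``beta1 = x3 (1 + alpha2)`` and
    ``beta2 = alpha1 / x2 - 1``).
    """
    if options is None:
        options = CalibrationOptions()
    merged = dict(options.fixed or {})
    merged.update(fixed)
    options = CalibrationOptions(
        tolerance=options.tolerance,
        multistart_grid=options.multistart_grid,
        fixed=merged,
        bounds=options.bounds,
        extra_starts=options.extra_starts,
        maxiter=options.maxiter,
    )
    return fit(vectors, options)


def identifiable_combinations(rates: TransitionRates) -> tuple:
    """The three steady-state-identifiable functions of the rates.

    ``s1 = alpha1 + beta1``, ``s2 = alpha1 / (1 + beta2)``,
    ``s3 = beta1 / (1 + alpha2)`` — equal to ``(1 - x1, x2, x3)`` of the
    stationary distribution.
    """
    return (
        rates.alpha1 + rates.beta1,
        rates.alpha1 / (1.0 + rates.beta2),
        rates.beta1 / (1.0 + rates.alpha2),
    )


def feasible_delta_interval(rates: TransitionRates) -> tuple:
    """Feasible shifts delta for :func:`equivalent_rates`.

    The binding constraints for realistic (small) rates are
    ``x2 - alpha1 <= delta <= beta1 - x3``, i.e.
    ``[-alpha1*beta2/(1+beta2), beta1*alpha2/(1+alpha2)]``; the remaining
    box constraints on the adjusted rates are intersected as well.
    """
    validate_rates(rates)
    a1, b1 = rates.alpha1, rates.beta1
    _, s2, s3 = identifiable_combinations(rates)
    lo = max(s2 - a1, b1 - 2.0 * s3, b1 - 1.0, -a1)
    hi = min(b1 - s3, 2.0 * s2 - a1, 1.0 - a1, b1)
    return lo, hi


def equivalent_rates(rates: TransitionRates, delta: float) -> TransitionRates:
    """A distinct rate vector with an identical steady state.

    Shifts ``alpha1 -> alpha1 + delta``, ``beta1 -> beta1 - delta`` and
    rescales ``alpha2``, ``beta2`` so that ``(s1, s2, s3)`` — hence the
    full stationary distribution — are unchanged.  A constructive witness
    that raw rates are not identifiable from steady-state data.

    Raises
    ------
    InfeasibleRatesError
        If ``delta`` falls outside :func:`feasible_delta_interval`, i.e.
        some adjusted rate would leave [0, 1].
    """
    validate_rates(rates)
    if delta == 0.0:
        return rates
    lo, hi = feasible_delta_interval(rates)
    if not (lo - 1e-15 <= delta <= hi + 1e-15):
        raise InfeasibleRatesError(
            f"delta={delta!r} outside the feasible interval [{lo:.6g}, {hi:.6g}]"
        )
    _, s2, s3 = identifiable_combinations(rates)
    if s2 <= 0.0 or s3 <= 0.0:
        raise InfeasibleRatesError(
            "equivalent rates require strictly positive CSF-naive and "
            "PB-differentiated stationary probabilities"
        )
    a1 = rates.alpha1 + delta
    b1 = rates.beta1 - delta
    return TransitionRates(
        alpha1=a1,
        alpha2=b1 / s3 - 1.0,
        beta1=b1,
        beta2=a1 / s2 - 1.0,
        cell_type=rates.cell_type,
        group=rates.group,
    ).validate()
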