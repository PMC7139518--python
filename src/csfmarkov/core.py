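"""Stationary stage distribution of the four-stage trafficking model.

With the total cell pool normalised to ``A0 = 1``, the stationary balance
equations for the stage probabilities ``x = (x1, x2, x3, x4)`` — PB/naive,
CSF/naive, PB/differentiated, CSF/differentiated — are::

    x1 = 1 - alpha1 - beta1
    (1 + beta2) * x2 = alpha1
    (1 + alpha2) * x3 = beta1
    x4 = beta2 * x2 + alpha2 * x3

which is a linear system ``A(alpha, beta) x = b(alpha, beta)`` whose matrix
and right-hand side depend linearly on the rates.  The solution sums to 1
identically (mass conservation) and is elementwise nonnegative whenever
``alpha1 + beta1 <= 1``.

The within-CSF differentiation terms use ``beta2``; a historical variant
in which the CSF-naive balance and the CSF inflow both use ``beta1``
instead is available via ``printed_variant=True``.  Both variants conserve
mass; only the ``beta2`` form matches the stage-diagram semantics in which
``beta2`` is differentiation inside the CSF, and it is the default and the
documented model throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateCompartmentError
from .rates import TransitionRates, validate_rates

__all__ = [
    "StageDistribution",
    "LinearSystem",
    "CompartmentProfile",
    "build_linear_system",
    "steady_state",
    "compartment_profile",
    "diff_fold_change",
    "compare_rates",
]

_CONSERVATION_TOL = 1e-12


@dataclass(frozen=True)
class StageDistribution:
    """Stationary probabilities over the four stages (sum to 1).

    ``x1`` PB/naive, ``x2`` CSF/naive, ``x3`` PB/differentiated,
    ``x4`` CSF/differentiated.  The total pool ``A0`` is fixed at 1;
    absolute cell numbers are obtained by external scaling.
    """

    x1: float
    x2: float
    x3: float
    x4: float

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < -_CONSERVATION_TOL):
            raise ValueError(f"negative stage probability in {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"stage probabilities sum to {arr.sum()!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4])


@dataclass(frozen=True)
class LinearSystem:
    """The 4x4 system ``A x = b`` whose solution is the stage distribution."""

    matrix: np.ndarray
    rhs: np.ndarray

    def solve(self) -> np.ndarray:
        return np.linalg.solve(self.matrix, self.rhs)


@dataclass(frozen=True)
class CompartmentProfile:
    """Naive/differentiated split renormalised within each compartment.

    Matches how flow-cytometry results are reported: percentages within
    PB and within CSF, plus the fraction of all modelled cells residing
    in each compartment (``pb_mass``, ``csf_mass``).
    """

    pb_naive_frac: float
    pb_diff_frac: float
    csf_naive_frac: float
    csf_diff_frac: float
    pb_mass: float
    csf_mass: float


def build_linear_system(
    rates: TransitionRates, printed_variant: bool = False
) -> LinearSystem:
    """Assemble ``A(alpha, beta)`` and ``b(alpha, beta)`` for valid rates.

    The matrix is invertible for all rates in [0, 1] (its determinant is
    ``(1 + b)(1 + alpha2)`` with ``b`` the within-CSF differentiation
    coefficient).
    """
    validate_rates(rates)
    a1, a2, b1, b2 = rates.alpha1, rates.alpha2, rates.beta1, rates.beta2
    b_csf = b1 if printed_variant else b2
    matrix = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0 + b_csf, 0.0, 0.0],
            [0.0, 0.0, 1.0 + a2, 0.0],
            [0.0, -b_csf, -a2, 1.0],
        ]
    )
    rhs = np.array([1.0 - a1 - b1, a1, b1, 0.0])
    return LinearSystem(matrix=matrix, rhs=rhs)


def steady_state(
    rates: TransitionRates, printed_variant: bool = False
) -> StageDistribution:
    """Closed-form stationary stage distribution.

    Evaluates ``x1 = 1 - alpha1 - beta1``, ``x2 = alpha1 / (1 + beta2)``,
    ``x3 = beta1 / (1 + alpha2)``, ``x4 = beta2 x2 + alpha2 x3``; the
    result solves the linear system of :func:`build_linear_system` and
    sums to 1 analytically.
    """
    validate_rates(rates)
    a1, a2, b1, b2 = rates.alpha1, rates.alpha2, rates.beta1, rates.beta2
    b_csf = b1 if printed_variant else b2
    x1 = 1.0 - a1 - b1
    x2 = a1 / (1.0 + b_csf)
    x3 = b1 / (1.0 + a2)
    x4 = b_csf * x2 + a2 * x3
    return StageDistribution(x1=x1, x2=x2, x3=x3, x4=x4)


def compartment_profile(dist: StageDistribution) -> CompartmentProfile:
    """Renormalise a stage distribution within each compartment.

    Raises
    ------
    DegenerateCompartmentError
        If either compartment carries zero mass, in which case the
        within-compartment fractions are undefined.
    """
    pb_mass = dist.x1 + dist.x3
    csf_mass = dist.x2 + dist.x4
    if pb_mass <= 0.0:
        raise DegenerateCompartmentError("PB compartment has zero mass")
    if csf_mass <= 0.0:
        raise DegenerateCompartmentError("CSF compartment has zero mass")
    return CompartmentProfile(
        pb_naive_frac=dist.x1 / pb_mass,
        pb_diff_frac=dist.x3 / pb_mass,
        csf_naive_frac=dist.x2 / csf_mass,
        csf_diff_frac=dist.x4 / csf_mass,
        pb_mass=pb_mass,
        csf_mass=csf_mass,
    )


def diff_fold_change(rates: TransitionRates) -> float:
    """Fold change of within-CSF over within-PB differentiation, beta2/beta1.

    A value above 1 means naive cells differentiate with higher
    probability inside the CSF than in the blood (e.g. about 1.9 for CD8
    T cells in non-inflammatory controls).
    """
    if rates.beta1 == 0.0:
        raise ZeroDivisionError("beta1 is zero; fold change undefined")
    return rates.beta2 / rates.beta1


def compare_rates(a: TransitionRates, b: TransitionRates) -> np.ndarray:
    """Elementwise fold changes a/b for (alpha1, alpha2, beta1, beta2).

    Used to quantify treatment effects, e.g. natalizumab suppressing the
    migration rates (alpha ratios well below 1) versus alemtuzumab raising
    the PB differentiation rate (beta1 ratio above 1).
    """
    denom = b.as_array()
    if np.any(denom == 0.0):
        raise ZeroDivisionError("all rates of the denominator must be nonzero")
    return a.as_array() / denom
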