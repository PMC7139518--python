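"""Transition rates for the four-stage lymphocyte trafficking model.

The model tracks one lymphocyte lineage across four stages: naive cells in
peripheral blood (PB), naive cells in cerebrospinal fluid (CSF),
differentiated cells in PB and differentiated cells in CSF.  Four
per-step transition probabilities connect them:

* ``alpha1`` — migration of naive cells from PB into the CSF,
* ``alpha2`` — migration of differentiated cells from PB into the CSF,
* ``beta1``  — differentiation (naive -> differentiated) within the PB,
* ``beta2``  — differentiation within the CSF.

Migration rates are *net* rates: recirculation from the CSF back to blood
is not represented separately.  All rates are stored as fractions in
[0, 1]; published tables print them as percentages and are converted at
the I/O boundary.

The module also packages a reference table of cohort-calibrated rates
(in percent) for the four lineages (CD4 and CD8 T cells, B cells, NK
cells) in five clinical groups: non-inflammatory controls, treatment-naive
relapsing-remitting MS (RRMS), RRMS under natalizumab or alemtuzumab, and
Susac syndrome (SuS).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InfeasibleRatesError, RateBoundsError, UnknownRatesError

__all__ = [
    "TransitionRates",
    "validate_rates",
    "reference_rates",
    "CELL_TYPES",
    "GROUPS",
    "RATE_NAMES",
    "REFERENCE_RATES_PERCENT",
]

RATE_NAMES = ("alpha1", "alpha2", "beta1", "beta2")
CELL_TYPES = ("CD4", "CD8", "B", "NK")
GROUPS = ("controls", "RRMS_naive", "RRMS_NAT", "RRMS_ALEM", "SuS")


@dataclass(frozen=True)
class TransitionRates:
    """The four transition rates for one lineage and patient group.

    Parameters
    ----------
    alpha1, alpha2, beta1, beta2 : float
        Fractions in [0, 1]; see module docstring for semantics.
    cell_type : str
        Lineage label, e.g. ``"CD8"``.
    group : str
        Patient-group label, e.g. ``"controls"``.
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    cell_type: str = ""
    group: str = ""

    def as_array(self) -> np.ndarray:
        """Rates as a length-4 array ordered (alpha1, alpha2, beta1, beta2)."""
        return np.array([self.alpha1, self.alpha2, self.beta1, self.beta2])

    @classmethod
    def from_array(cls, arr, cell_type: str = "", group: str = "") -> "TransitionRates":
        a1, a2, b1, b2 = (float(v) for v in arr)
        return cls(a1, a2, b1, b2, cell_type=cell_type, group=group)

    @classmethod
    def from_percent(
        cls, alpha1, alpha2, beta1, beta2, cell_type: str = "", group: str = ""
    ) -> "TransitionRates":
        """Build from printed percentage values (divided by 100)."""
        return cls(
            alpha1 / 100.0,
            alpha2 / 100.0,
            beta1 / 100.0,
            beta2 / 100.0,
            cell_type=cell_type,
            group=group,
        )

    def replace(self, **kwargs) -> "TransitionRates":
        return replace(self, **kwargs)

    def validate(self) -> "TransitionRates":
        return validate_rates(self)


def validate_rates(rates: TransitionRates) -> TransitionRates:
    """Check rate bounds and stage-1 feasibility; return the input unchanged.

    Each rate must lie in [0, 1], and ``alpha1 + beta1 <= 1`` so that the
    stationary probability of the PB-naive stage, ``1 - alpha1 - beta1``,
    is nonnegative.

    Raises
    ------
    RateBoundsError
        If any single rate is outside [0, 1]; the message names it.
    InfeasibleRatesError
        If ``alpha1 + beta1 > 1``.
    """
    for name in RATE_NAMES:
        value = getattr(rates, name)
        if not np.isfinite(value) or value < 0.0 or value > 1.0:
            raise RateBoundsError(
                f"rate {name}={value!r} outside [0, 1] "
                f"(cell_type={rates.cell_type!r}, group={rates.group!r})"
            )
    if rates.alpha1 + rates.beta1 > 1.0:
        raise InfeasibleRatesError(
            f"alpha1 + beta1 = {rates.alpha1 + rates.beta1:.6g} > 1: "
            "the PB-naive stage would have negative stationary probability"
        )
    return rates


# Published cohort-calibrated transition rates, in percent, for each
# lineage x group.  Row order per lineage: alpha1, alpha2, beta1, beta2;
# column order follows GROUPS.
REFERENCE_RATES_PERCENT: dict[tuple[str, str], tuple[float, float, float, float]] = {}

_TABLE = {
    "CD4": {
        "alpha1": (0.111389, 0.586281, 0.0532484, 0.796713, 0.200412),
        "alpha2": (0.0911057, 0.472904, 0.104328, 0.579225, 0.14176),
        "beta1": (6.36074, 6.97785, 5.56686, 16.5061, 9.53956),
        "beta2": (4.94663, 5.36697, 9.84513, 10.7709, 6.32671),
    },
    "CD8": {
        "alpha1": (0.120849, 0.743036, 0.16279, 1.38373, 0.144033),
        "alpha2": (0.280367, 1.68937, 0.383813, 2.36217, 0.196247),
        "beta1": (10.5938, 12.6372, 8.48535, 22.0888, 22.3179),
        "beta2": (19.7744, 22.4608, 16.7073, 27.9459, 23.472),
    },
    "B": {
        "alpha1": (0.00624261, 0.163174, 0.00734096, 0.114144, 0.034936),
        "alpha2": (0.517731, 2.05505, 0.756185, 4.19525, 0.628489),
        "beta1": (0.512537, 0.706717, 0.539675, 0.290181, 1.07631),
        "beta2": (29.9383, 8.32669, 35.9123, 10.0614, 16.3201),
    },
    "NK": {
        "alpha1": (0.00960978, 0.083438, 0.00982681, 0.143154, 0.012265),
        "alpha2": (0.0035751, 0.008764, 0.00583337, 0.013084, 0.007612),
        "beta1": (93.6461, 92.5525, 88.5722, 78.6259, 92.6465),
        "beta2": (25.7994, 8.89219, 34.558, 6.71746, 36.57),
    },
}

for _ct, _rows in _TABLE.items():
    for _j, _grp in enumerate(GROUPS):
        REFERENCE_RATES_PERCENT[(_ct, _grp)] = tuple(
            _rows[name][_j] for name in RATE_NAMES
        )
del _TABLE, _ct, _rows, _j, _grp


def reference_rates(cell_type: str, group: str) -> TransitionRates:
    """Packaged published transition rates for one lineage and group.

    Values are stored in percent and returned as fractions.

    Parameters
    ----------
    cell_type : {"CD4", "CD8", "B", "NK"}
    group : {"controls", "RRMS_naive", "RRMS_NAT", "RRMS_ALEM", "SuS"}

    Raises
    ------
    UnknownRatesError
        For an unknown key; the message lists the valid keys.
    """
    key = (cell_type, group)
    if key not in REFERENCE_RATES_PERCENT:
        raise UnknownRatesError(
            f"no reference rates for {key!r}; valid cell types are "
            f"{CELL_TYPES} and groups {GROUPS}"
        )
    a1, a2, b1, b2 = REFERENCE_RATES_PERCENT[key]
    return TransitionRates.from_percent(a1, a2, b1, b2, cell_type=cell_type, group=group)
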