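"""CSV input/output for cohorts and rate tables.

Files carry percentages (as published tables and flow-cytometry reports
do); memory carries fractions.  Conversion happens only at this
boundary.  Numeric values are written with 6 significant digits, and
``write(read(x))`` is byte-stable for files the package wrote itself.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord
from .exceptions import CohortParseError
from .rates import (
    CELL_TYPES,
    GROUPS,
    RATE_NAMES,
    REFERENCE_RATES_PERCENT,
    TransitionRates,
)

__all__ = [
    "RatesTable",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_rates",
    "write_rates",
    "reference_rates_table",
]

_REQUIRED_COHORT_COLUMNS = (
    "patient_id",
    "group",
    "cell_type",
    "pb_naive_pct",
    "pb_diff_pct",
    "csf_naive_pct",
    "csf_diff_pct",
)
_OPTIONAL_COHORT_COLUMNS = ("pb_total_count", "csf_total_count")
# Rounded published-style tables can miss 100 by a little; pairs off by
# more than this are treated as data errors rather than rounding.
_PAIR_SUM_SLACK = 0.5


def _fmt(value: float) -> str:
    return format(float(value), ".6g")


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort in the canonical CSV schema (percent units)."""
    rows = []
    for rec in cohort:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "group": rec.group,
                "cell_type": rec.cell_type,
                "pb_naive_pct": _fmt(rec.pb_naive_pct),
                "pb_diff_pct": _fmt(rec.pb_diff_pct),
                "csf_naive_pct": _fmt(rec.csf_naive_pct),
                "csf_diff_pct": _fmt(rec.csf_diff_pct),
                "pb_total_count": "" if rec.pb_total_count is None else rec.pb_total_count,
                "csf_total_count": "" if rec.csf_total_count is None else rec.csf_total_count,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    """Read and validate a cohort CSV.

    Percentage pairs within 0.5 of 100 are renormalised to exactly 100;
    pairs further off raise :class:`CohortParseError` naming the row
    (1-based, excluding the header).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CohortParseError(f"cannot read cohort CSV {path!r}: {exc}") from exc
    missing = [c for c in _REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"missing required column(s) {missing} in {path!r}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        values = {}
        for col in _REQUIRED_COHORT_COLUMNS[3:]:
            raw = getattr(row, col)
            try:
                values[col] = float(raw)
            except (TypeError, ValueError):
                raise CohortParseError(
                    f"row {i}: non-numeric value {raw!r} in column {col!r}"
                ) from None
            if np.isnan(values[col]):
                raise CohortParseError(f"row {i}: missing value in column {col!r}")
        pairs = {}
        for label, (a, b) in {
            "pb": (values["pb_naive_pct"], values["pb_diff_pct"]),
            "csf": (values["csf_naive_pct"], values["csf_diff_pct"]),
        }.items():
            total = a + b
            if abs(total - 100.0) > _PAIR_SUM_SLACK:
                raise CohortParseError(
                    f"row {i}: {label} percentages sum to {total:.4g}, "
                    f"more than {_PAIR_SUM_SLACK} away from 100"
                )
            if abs(total - 100.0) > 1e-9:
                a, b = 100.0 * a / total, 100.0 * b / total
            pairs[label] = (a, b)
        counts = {}
        for col in _OPTIONAL_COHORT_COLUMNS:
            raw = getattr(row, col, None)
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                counts[col] = None
            else:
                try:
                    counts[col] = int(raw)
                except (TypeError, ValueError):
                    raise CohortParseError(
                        f"row {i}: non-integer count {raw!r} in column {col!r}"
                    ) from None
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    group=str(row.group),
                    cell_type=str(row.cell_type),
                    pb_naive_pct=pairs["pb"][0],
                    pb_diff_pct=pairs["pb"][1],
                    csf_naive_pct=pairs["csf"][0],
                    csf_diff_pct=pairs["csf"][1],
                    pb_total_count=counts["pb_total_count"],
                    csf_total_count=counts["csf_total_count"],
                )
            )
        except ValueError as exc:
            raise CohortParseError(f"row {i}: {exc}") from exc
    if not records:
        raise CohortParseError(f"cohort file {path!r} contains no records")
    return Cohort(records=tuple(records))


@dataclass(frozen=True)
class RatesTable:
    """A (cell_type, group) -> TransitionRates mapping with layout metadata.

    Values are held as fractions regardless of the file units; ``units``
    records how the backing file expresses them.
    """

    mapping: dict
    units: str = "percent"
    cell_types: tuple = field(default=CELL_TYPES)
    groups: tuple = field(default=GROUPS)

    def get(self, cell_type: str, group: str) -> TransitionRates:
        return self.mapping[(cell_type, group)]


def reference_rates_table() -> RatesTable:
    """The packaged published rate table as a :class:`RatesTable`."""
    mapping = {
        (ct, grp): TransitionRates.from_percent(*vals, cell_type=ct, group=grp)
        for (ct, grp), vals in REFERENCE_RATES_PERCENT.items()
    }
    return RatesTable(mapping=mapping)


def write_rates(table: RatesTable, path) -> None:
    """Write a rate table CSV (rows = cell_type x rate, columns = groups).

    The first line records the units, e.g. ``# units: percent``.
    """
    scale = 100.0 if table.units == "percent" else 1.0
    lines = [f"# units: {table.units}", "cell_type,rate," + ",".join(table.groups)]
    for ct in table.cell_types:
        for j, name in enumerate(RATE_NAMES):
            vals = [
                _fmt(table.mapping[(ct, grp)].as_array()[j] * scale)
                for grp in table.groups
            ]
            lines.append(f"{ct},{name}," + ",".join(vals))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_rates(path) -> RatesTable:
    """Read a rate table CSV written by :func:`write_rates`."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        rest = fh.read()
    units = "percent"
    if first.startswith("#"):
        units = first.split(":", 1)[1].strip() if ":" in first else "percent"
    else:
        rest = first + "\n" + rest
    if units not in ("percent", "fraction"):
        raise CohortParseError(f"unknown units {units!r} in {path!r}")
    df = pd.read_csv(_io.StringIO(rest))
    for col in ("cell_type", "rate"):
        if col not in df.columns:
            raise CohortParseError(f"missing column {col!r} in rate table {path!r}")
    groups = tuple(c for c in df.columns if c not in ("cell_type", "rate"))
    limit = 100.0 if units == "percent" else 1.0
    scale = 1.0 / limit

    values: dict = {}
    cell_types = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.rate not in RATE_NAMES:
            raise CohortParseError(
                f"row {i}: unknown rate label {row.rate!r} (expected one of {RATE_NAMES})"
            )
        if row.cell_type not in cell_types:
            cell_types.append(row.cell_type)
        for grp in groups:
            v = float(getattr(row, grp))
            if not 0.0 <= v <= limit:
                raise CohortParseError(
                    f"row {i}: value {v!r} outside [0, {limit:g}] ({units})"
                )
            values.setdefault((row.cell_type, grp), {})[row.rate] = v * scale

    mapping = {}
    for (ct, grp), d in values.items():
        missing = [n for n in RATE_NAMES if n not in d]
        if missing:
            raise CohortParseError(f"({ct}, {grp}): missing rate(s) {missing}")
        mapping[(ct, grp)] = TransitionRates(
            **{n: d[n] for n in RATE_NAMES}, cell_type=ct, group=grp
        ).validate()
    return RatesTable(
        mapping=mapping, units=units, cell_types=tuple(cell_types), groups=groups
    )
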