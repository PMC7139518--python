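"""Patient records, cohorts and the synthetic-cohort generator.

Real inputs are per-patient flow-cytometry summaries: for one lineage,
the naive and differentiated percentages within peripheral blood and
within CSF, plus optional absolute cell counts per compartment.  The
generator emulates such records from known transition rates so that
calibration and prediction can be exercised end to end without patient
data: it computes the model's compartment profile, draws the number of
naive events per compartment from a binomial with the flow-cytometry
event count as the number of trials (the dominant noise source in gated
percentages), and optionally jitters the generating rates per patient on
the logit scale to emulate inter-patient heterogeneity.

The default event counts — 10,000 events in blood, 200 in CSF — reflect
that CSF samples are paucicellular: percentage noise is an order of
magnitude larger in the CSF than in blood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import compartment_profile, steady_state
from .exceptions import InfeasibleRatesError
from .rates import TransitionRates, validate_rates

__all__ = [
    "PatientRecord",
    "Cohort",
    "GeneratorConfig",
    "generate_patient",
    "generate_cohort",
]

_PAIR_TOL = 1e-6
_MAX_JITTER_RETRIES = 100


@dataclass(frozen=True)
class PatientRecord:
    """One patient's gated percentages for a single lineage.

    Two layouts are accepted: the usual per-compartment one, in which
    ``pb_naive_pct + pb_diff_pct`` and ``csf_naive_pct + csf_diff_pct``
    each sum to 100, and a joint one in which the four percentages
    together sum to 100 (``is_joint``), already forming a distribution
    over all four stages.  Absolute counts per compartment are optional;
    they are required only for count-weighted stage-vector assembly.
    """

    patient_id: str
    group: str
    cell_type: str
    pb_naive_pct: float
    pb_diff_pct: float
    csf_naive_pct: float
    csf_diff_pct: float
    pb_total_count: Optional[int] = None
    csf_total_count: Optional[int] = None

    def __post_init__(self):
        four = (
            self.pb_naive_pct,
            self.pb_diff_pct,
            self.csf_naive_pct,
            self.csf_diff_pct,
        )
        for label, v in zip(
            ("pb_naive_pct", "pb_diff_pct", "csf_naive_pct", "csf_diff_pct"), four
        ):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{label} = {v} outside [0, 100]")
        pairwise = (
            abs(self.pb_naive_pct + self.pb_diff_pct - 100.0) <= _PAIR_TOL
            and abs(self.csf_naive_pct + self.csf_diff_pct - 100.0) <= _PAIR_TOL
        )
        if not pairwise and abs(sum(four) - 100.0) > _PAIR_TOL:
            raise ValueError(
                f"percentages {four} neither sum to 100 pairwise per "
                "compartment nor jointly across the four stages"
            )
        for label, count in (
            ("pb_total_count", self.pb_total_count),
            ("csf_total_count", self.csf_total_count),
        ):
            if count is not None and count < 0:
                raise ValueError(f"{label} = {count} is negative")

    @property
    def is_joint(self) -> bool:
        """True if the four percentages jointly (not pairwise) sum to 100."""
        return (
            abs(self.pb_naive_pct + self.pb_diff_pct - 100.0) > _PAIR_TOL
            or abs(self.csf_naive_pct + self.csf_diff_pct - 100.0) > _PAIR_TOL
        )


@dataclass(frozen=True)
class Cohort:
    """A nonempty list of records for one lineage.

    ``generating_rates`` holds the ground truth when the cohort is
    synthetic, enabling parameter-recovery checks.
    """

    records: tuple[PatientRecord, ...]
    generating_rates: Optional[TransitionRates] = None

    def __post_init__(self):
        if len(self.records) == 0:
            raise ValueError("cohort must contain at least one record")
        cell_types = {r.cell_type for r in self.records}
        if len(cell_types) > 1:
            raise ValueError(f"cohort mixes cell types {sorted(cell_types)}")
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def cell_type(self) -> str:
        return self.records[0].cell_type


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-cohort generation settings.

    ``n_pb_events`` / ``n_csf_events`` are flow-cytometry event counts
    per compartment (binomial trials for the gated percentages);
    ``total_cells`` scales the absolute counts; ``heterogeneity_sd`` is
    the SD of a per-patient Gaussian jitter applied to each rate on the
    logit scale (0 disables it).
    """

    n_patients: int = 75
    n_pb_events: int = 10_000
    n_csf_events: int = 200
    total_cells: float = 1e6
    heterogeneity_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_pb_events < 1 or self.n_csf_events < 1:
            raise ValueError("event counts must be >= 1")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")


def _logit_jitter(rates: TransitionRates, sd: float, rng: np.random.Generator):
    """Jitter each rate on the logit scale; rates exactly 0 or 1 stay put.

    Redraws (bounded) if the jittered pair violates alpha1 + beta1 <= 1.
    """
    base = rates.as_array()
    for _ in range(_MAX_JITTER_RETRIES):
        noise = rng.normal(0.0, sd, size=4)
        out = base.copy()
        interior = (base > 0.0) & (base < 1.0)
        logit = np.log(base[interior] / (1.0 - base[interior]))
        out[interior] = 1.0 / (1.0 + np.exp(-(logit + noise[interior])))
        if out[0] + out[2] <= 1.0:
            return TransitionRates.from_array(
                out, cell_type=rates.cell_type, group=rates.group
            )
    raise InfeasibleRatesError(
        f"jittered rates violated alpha1 + beta1 <= 1 in "
        f"{_MAX_JITTER_RETRIES} consecutive draws (sd={sd})"
    )


def generate_patient(
    rates: TransitionRates, config: GeneratorConfig, patient_index: int
) -> PatientRecord:
    """Draw one synthetic patient record.

    Reproducible: the random stream is keyed on ``(config.seed,
    patient_index)``, so regenerating any single patient gives an
    identical record regardless of cohort size.
    """
    validate_rates(rates)
    rng = np.random.default_rng([config.seed, patient_index])
    patient_rates = rates
    if config.heterogeneity_sd > 0.0:
        patient_rates = _logit_jitter(rates, config.heterogeneity_sd, rng)
    profile = compartment_profile(steady_state(patient_rates))

    pb_naive_events = rng.binomial(config.n_pb_events, profile.pb_naive_frac)
    csf_naive_events = rng.binomial(config.n_csf_events, profile.csf_naive_frac)
    pb_naive_pct = 100.0 * pb_naive_events / config.n_pb_events
    csf_naive_pct = 100.0 * csf_naive_events / config.n_csf_events

    return PatientRecord(
        patient_id=f"S{patient_index:04d}",
        group=rates.group or "synthetic",
        cell_type=rates.cell_type or "unknown",
        pb_naive_pct=pb_naive_pct,
        pb_diff_pct=100.0 - pb_naive_pct,
        csf_naive_pct=csf_naive_pct,
        csf_diff_pct=100.0 - csf_naive_pct,
        pb_total_count=int(round(config.total_cells * profile.pb_mass)),
        csf_total_count=int(round(config.total_cells * profile.csf_mass)),
    )


def generate_cohort(rates: TransitionRates, config: GeneratorConfig) -> Cohort:
    """Generate ``config.n_patients`` records; ground truth is stored on
    the cohort as ``generating_rates``."""
    records = tuple(
        generate_patient(rates, config, i) for i in range(config.n_patients)
    )
    return Cohort(records=records, generating_rates=rates)
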