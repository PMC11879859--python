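"""Core data containers for the trial analysis pipeline.

The trial table is held as a pandas DataFrame with one row per participant
and a documented column schema (see :data:`TRIAL_COLUMNS`).  Clinical
measurements keep the units in which they were recorded (glucose mmol/l,
insulin mIE/l, C-peptide nmol/l, HbA1c mmol/mol, triglycerides mmol/l,
GGT μkat/l, serum sulforaphane nmol/ml); unit conversions happen inside the
index formulas, never at I/O time.  Missing values are plain NaN / empty
CSV cells — participants who discontinued before week 12 have partial rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ARMS = ("BSE", "placebo")

#: clinical variables recorded at both visits
VISIT_VARS = (
    "glucose",
    "insulin",
    "c_peptide",
    "hba1c",
    "bmi",
    "waist",
    "triglycerides",
    "ggt",
)

#: canonical column order of the participant table
TRIAL_COLUMNS = (
    ["participant_id", "arm", "completed", "age", "height", "weight"]
    + [f"baseline_{v}" for v in VISIT_VARS]
    + [f"week12_{v}" for v in VISIT_VARS]
    + ["serum_sulforaphane"]
)

#: mandatory subset — the rest may be absent in minimal tables
REQUIRED_COLUMNS = (
    "participant_id",
    "arm",
    "completed",
    "baseline_glucose",
)


class SchemaError(ValueError):
    """A table violates the documented participant-table schema."""


class DomainError(ValueError):
    """A value is outside the domain of a formula or invariant."""


@dataclass
class ParticipantRecord:
    """One participant's measurements in natural units."""

    participant_id: str
    arm: str
    completed: bool
    baseline: dict = field(default_factory=dict)
    week12: dict = field(default_factory=dict)
    age: Optional[float] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    serum_sulforaphane: Optional[float] = None


@dataclass
class TrialDataset:
    """Participant table plus provenance metadata.

    ``latent`` holds generator-only ground truth (true cluster, true
    sulforaphane component) aligned on participant_id.  It is never written
    by :func:`bsetrial.io.write_trial_table`.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    latent: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        validate_trial_table(self.table)

    @property
    def n(self) -> int:
        return len(self.table)

    def completers(self) -> pd.DataFrame:
        """Full-analysis-set rows: participants with post-randomization
        clinical measures (week-12 glucose present)."""
        return self.table[self.table["completed"].astype(bool)]

    def arm_table(self, arm: str) -> pd.DataFrame:
        if arm not in ARMS:
            raise DomainError(f"unknown arm {arm!r}; expected one of {ARMS}")
        return self.table[self.table["arm"] == arm]

    def records(self):
        for _, row in self.table.iterrows():
            yield ParticipantRecord(
                participant_id=row["participant_id"],
                arm=row["arm"],
                completed=bool(row["completed"]),
                baseline={v: row.get(f"baseline_{v}", np.nan) for v in VISIT_VARS},
                week12={v: row.get(f"week12_{v}", np.nan) for v in VISIT_VARS},
                age=row.get("age"),
                height=row.get("height"),
                weight=row.get("weight"),
                serum_sulforaphane=row.get("serum_sulforaphane"),
            )


def validate_trial_table(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` on invariant violations, with row-level
    diagnostics where applicable."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if len(dup):
        raise SchemaError(
            f"participant_id not unique: {sorted(set(dup.astype(str)))}"
        )
    bad_arm = df.loc[~df["arm"].isin(ARMS), "participant_id"]
    if len(bad_arm):
        raise SchemaError(
            f"unknown arm for participants {list(bad_arm.astype(str))}; "
            f"expected one of {ARMS}"
        )
    glu = pd.to_numeric(df["baseline_glucose"], errors="coerce")
    nonpos = df.loc[glu <= 0, "participant_id"]
    if len(nonpos):
        raise SchemaError(
            f"non-positive baseline glucose for {list(nonpos.astype(str))}"
        )
    if "baseline_bmi" in df.columns:
        bmi = pd.to_numeric(df["baseline_bmi"], errors="coerce")
        nonpos = df.loc[bmi <= 0, "participant_id"]
        if len(nonpos):
            raise SchemaError(
                f"non-positive BMI for {list(nonpos.astype(str))}"
            )
    # week-12 fields may be absent only for non-completers
    if "week12_glucose" in df.columns:
        completed = df["completed"].astype(bool)
        missing = df["week12_glucose"].isna() & completed
        if missing.any():
            ids = list(df.loc[missing, "participant_id"].astype(str))
            raise SchemaError(
                f"completers without week-12 glucose: {ids}"
            )


@dataclass
class RunConfig:
    """Run-level configuration shared by the pipeline stages."""

    seed: int = 0
    bootstrap_rounds: int = 1000
    n_permutations: int = 10_000
    responder_threshold_mode: str = "fixed"
    feature_set: tuple = ("bmi", "age", "glucose", "c_peptide", "hba1c")
    k: int = 4

    def __post_init__(self) -> None:
        if self.bootstrap_rounds < 1:
            raise DomainError("bootstrap_rounds must be >= 1")
        if self.n_permutations < 1:
            raise DomainError("n_permutations must be >= 1")
        if self.k < 2:
            raise DomainError("k must be >= 2")
        if self.responder_threshold_mode not in ("fixed", "quantile"):
            raise DomainError(
                "responder_threshold_mode must be 'fixed' or 'quantile'"
            )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
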