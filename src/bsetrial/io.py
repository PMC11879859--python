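"""Readers and writers for participant tables and abundance tables.

CSV is the native dialect for participant tables (TSV accepted); abundance
tables are TSV with features as rows, samples as columns, and the feature id
in the first column.  Floats are written with ``repr`` round-trip precision
so that write → read is value-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datamodel import TRIAL_COLUMNS, SchemaError, TrialDataset, validate_trial_table

log = logging.getLogger("bsetrial")

_DELIMS = {"csv": ",", "tsv": "\t"}


def _sep(path: Union[str, Path], dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in _DELIMS:
            raise ValueError(f"unknown dialect {dialect!r}")
        return _DELIMS[dialect]
    return _DELIMS["tsv"] if str(path).endswith((".tsv", ".tab")) else _DELIMS["csv"]


def read_trial_table(path: Union[str, Path], dialect: str | None = None) -> TrialDataset:
    """Read and validate a participant table.

    Raises :class:`SchemaError` for missing mandatory columns or invariant
    violations and ``ValueError`` naming the row for unparsable numerics.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path, dialect), dtype={"participant_id": str})
    numeric_cols = [
        c for c in df.columns if c not in ("participant_id", "arm", "completed")
    ]
    for col in numeric_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[bad.isna() & df[col].notna()].tolist()
            raise ValueError(
                f"non-numeric value in column {col!r} at row(s) {rows}"
            ) from None
    if "completed" in df.columns:
        df["completed"] = df["completed"].astype(bool)
    validate_trial_table(df)
    return TrialDataset(table=df, metadata={"source": str(path)})


def write_trial_table(dataset: TrialDataset, path: Union[str, Path]) -> None:
    """Write the observed participant table (never latent columns) with a
    stable column order and lossless float formatting."""
    path = Path(path)
    df = dataset.table
    ordered = [c for c in TRIAL_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in TRIAL_COLUMNS
    ]
    df[ordered].to_csv(path, sep=_sep(path, None), index=False)
    log.info("wrote trial table with %d rows to %s", len(df), path)


def read_abundance_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a features-as-rows TSV abundance table into a samples × features
    DataFrame (transposed to the in-memory convention)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise SchemaError("duplicate feature ids in abundance table")
    table = df.T
    if (table.to_numpy() < 0).any():
        raise SchemaError("negative abundance values")
    table.index.name = "sample_id"
    return table


def write_abundance_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a samples × features DataFrame in the features-as-rows TSV
    convention."""
    out = table.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def write_distance_matrix(dm: np.ndarray, ids, path: Union[str, Path]) -> None:
    pd.DataFrame(dm, index=ids, columns=ids).to_csv(path, sep="\t")
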