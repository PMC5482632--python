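"""Readers and writers for the package's plain-text formats.

Expression matrices are tab-delimited: first column holds probe/gene ids, the
header row holds sample ids, cells hold intensities (empty cell = missing).
Clinical cohorts are CSV with at least ``time`` (months, > 0) and ``event``
(one of ``relapse``/``death``/``censored``) columns; any further columns are
covariates.  Probe annotations are two-column TSV (probe, gene).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pandas.errors import ParserError

from .containers import ExpressionMatrix
from .errors import DataError
from .survival import _check_records

__all__ = [
    "read_expression",
    "write_expression",
    "read_probe_map",
    "read_clinical",
    "write_clinical",
]


def _infer_conditions(samples: pd.Index) -> pd.Series:
    """Condition = sample-id prefix before the last underscore."""
    return pd.Series(
        [s.rsplit("_", 1)[0] if "_" in s else "all" for s in samples],
        index=samples,
        name="condition",
    )


def read_expression(
    path: str | Path,
    annotation: str | Path | pd.Series | None = None,
    conditions: str | Path | dict | pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited intensity matrix (probes x samples).

    ``annotation`` maps probes to genes (two-column TSV, or a Series); when
    omitted, rows are treated as genes (identity mapping).  ``conditions``
    maps samples to condition labels (two-column file, dict or Series); when
    omitted the condition is inferred from the sample-id prefix before the
    last underscore (the convention used by :func:`rbescreen.simulate.gen_expression`).
    """
    path = Path(path)
    with open(path) as fh:  # pandas silently renames duplicate headers
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise DataError(f"{path}: duplicate sample ids in the header: {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ParserError as exc:
        raise DataError(f"{path}: malformed table: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate row ids: {dups[:10]}")
    if df.columns.has_duplicates or any(str(c).startswith("Unnamed") for c in df.columns):
        raise DataError(f"{path}: duplicate or unnamed sample ids in the header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row_pos = int(np.argmax(bad.any(axis=1).to_numpy()))
        col = bad.columns[bad.iloc[row_pos].to_numpy()][0]
        raise DataError(
            f"{path}: non-numeric value {df.iloc[row_pos][col]!r} "
            f"at line {row_pos + 2}, sample {col!r}"
        )

    if annotation is None:
        probe_to_gene = pd.Series(numeric.index, index=numeric.index, name="gene")
    elif isinstance(annotation, pd.Series):
        probe_to_gene = annotation
    else:
        probe_to_gene = read_probe_map(annotation)

    if conditions is None:
        condition = _infer_conditions(numeric.columns)
    elif isinstance(conditions, pd.Series):
        condition = conditions
    elif isinstance(conditions, dict):
        condition = pd.Series(conditions, name="condition")
    else:
        cond_df = pd.read_csv(conditions, sep=None, engine="python")
        condition = pd.Series(
            cond_df.iloc[:, 1].to_numpy(), index=cond_df.iloc[:, 0], name="condition"
        )

    return ExpressionMatrix(
        values=numeric, probe_to_gene=probe_to_gene, condition=condition, meta={"path": str(path)}
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the intensity matrix as tab-delimited text (round-trips exactly:
    pandas writes full-precision reprs that parse back to the same float64)."""
    matrix.values.rename_axis("id").to_csv(path, sep="\t")


def read_probe_map(path: str | Path) -> pd.Series:
    """Two-column probe -> gene annotation table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError(f"{path}: annotation needs two columns (probe, gene)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="gene")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical cohort CSV (time, event, covariates...)."""
    df = pd.read_csv(path)
    return _check_records(df)


def write_clinical(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)
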