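"""Rank-based cross-platform differential-expression screening.

Microarray intensities from different platforms are not directly comparable,
but the *ordering* of genes within one array is.  This module therefore works
on per-sample percentile rank scores (1..100): each sample's intensities are
ranked and mapped onto a common 1-100 scale, the per-gene mean of those scores
over a condition's samples is the **average rank score (ARS)**, and the
difference of ARS between two conditions (case minus control) is the **delta**
statistic used to screen for differentially expressed genes.  Because every
step after ranking depends only on within-sample order, the whole chain is
invariant under any per-sample strictly increasing distortion — which is what
makes the screen platform-robust.

The default screen retains genes with ``delta > 45`` and ``ARS_case > 80``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import rankdata

from .containers import ExpressionMatrix, RankMatrix
from .errors import DataError

__all__ = [
    "rank_transform",
    "collapse_probes",
    "average_rank_score",
    "delta_score",
    "score_genes",
    "screen_genes",
    "rbe_curve",
    "gpl_score",
]


def _rank_scores_1d(values: np.ndarray) -> np.ndarray:
    """Map one sample's intensities to percentile rank scores in [1, 100].

    Ascending ordinal rank k of N maps to ceil(100*k/N); tied intensities
    receive the mean of their mapped scores.  NaN entries stay NaN.
    """
    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    n = int(mask.sum())
    if n == 0:
        return out
    v = values[mask]
    ordinal = rankdata(v, method="ordinal")
    scores = np.ceil(100.0 * ordinal / n)
    # average mapped scores within tied groups
    s = pd.Series(scores).groupby(pd.Series(v)).transform("mean").to_numpy()
    out[mask] = s
    return out


def rank_transform(matrix: ExpressionMatrix) -> RankMatrix:
    """Transform intensities to per-sample percentile rank scores (1..100).

    Each sample (column) is ranked independently, so the result is invariant
    to any strictly increasing per-sample transformation of the intensities.

    Raises
    ------
    DataError
        If a sample has no finite values (the offending sample is named).
    """
    vals = matrix.values.to_numpy(dtype=float)
    finite_per_sample = np.isfinite(vals).sum(axis=0)
    if (finite_per_sample == 0).any():
        bad = matrix.values.columns[finite_per_sample == 0].tolist()
        raise DataError(f"samples with no finite values: {bad}")
    ranked = np.column_stack([_rank_scores_1d(vals[:, j]) for j in range(vals.shape[1])])
    return RankMatrix(
        values=pd.DataFrame(ranked, index=matrix.values.index, columns=matrix.values.columns),
        probe_to_gene=matrix.probe_to_gene.copy(),
        condition=matrix.condition.copy(),
        meta=dict(matrix.meta),
    )


def collapse_probes(rm: RankMatrix) -> RankMatrix:
    """Collapse a probe-level rank matrix to gene level.

    For genes measured by several probes, the single probe with the maximal
    ARS pooled over *all* samples (both conditions) represents the gene, so
    the same probe is used on each side of the comparison.  Ties are broken
    by probe id (lexicographic) for determinism.  Probes with no gene mapping
    are dropped with a warning; the count is recorded in ``meta``.
    """
    mapped = rm.probe_to_gene.notna()
    n_dropped = int((~mapped).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} probes without a gene mapping", stacklevel=2)
    values = rm.values.loc[mapped.to_numpy()]
    genes = rm.probe_to_gene[mapped]

    pooled_ars = values.mean(axis=1, skipna=True)
    choice = (
        pd.DataFrame({"gene": genes.to_numpy(), "ars": pooled_ars.to_numpy()}, index=values.index)
        .rename_axis("probe")
        .reset_index()
        .sort_values(["gene", "ars", "probe"], ascending=[True, False, True], kind="mergesort")
        .groupby("gene", sort=True)
        .head(1)
    )
    collapsed = values.loc[choice["probe"]]
    collapsed.index = pd.Index(choice["gene"], name="gene")
    meta = dict(rm.meta)
    meta["n_unmapped_probes_dropped"] = n_dropped
    meta["representative_probe"] = dict(zip(choice["gene"], choice["probe"]))
    return RankMatrix(
        values=collapsed,
        probe_to_gene=pd.Series(collapsed.index, index=collapsed.index),
        condition=rm.condition.copy(),
        meta=meta,
    )


def average_rank_score(rm: RankMatrix, gene: str, condition: str) -> float:
    """Mean rank score of ``gene`` over the samples of ``condition``."""
    if gene not in rm.values.index:
        raise DataError(f"gene {gene!r} not present")
    scores = rm.values.loc[gene, rm.samples_in(condition)]
    if scores.notna().sum() == 0:
        raise DataError(f"gene {gene!r} has no non-missing samples in {condition!r}")
    return float(scores.mean())


def delta_score(ars_case: float, ars_control: float) -> float:
    """Difference of average rank scores, case minus control."""
    for name, v in (("ars_case", ars_case), ("ars_control", ars_control)):
        if not 1.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [1, 100]")
    return ars_case - ars_control


def score_genes(
    rm: RankMatrix,
    case: str,
    control: str,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Per-gene ARS in both conditions and the delta statistic.

    Genes with fewer than ``min_samples`` non-missing values in either
    condition are excluded (pairwise-complete scoring).

    Returns a DataFrame indexed by gene with columns
    ``ars_case, ars_control, delta, n_case, n_control``.
    """
    case_cols = rm.samples_in(case)
    ctrl_cols = rm.samples_in(control)
    case_vals = rm.values[case_cols]
    ctrl_vals = rm.values[ctrl_cols]
    out = pd.DataFrame(
        {
            "ars_case": case_vals.mean(axis=1, skipna=True),
            "ars_control": ctrl_vals.mean(axis=1, skipna=True),
            "n_case": case_vals.notna().sum(axis=1),
            "n_control": ctrl_vals.notna().sum(axis=1),
        }
    )
    keep = (out["n_case"] >= min_samples) & (out["n_control"] >= min_samples)
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} genes with <{min_samples} "
            "non-missing samples in a condition",
            stacklevel=2,
        )
    out = out[keep].copy()
    out["delta"] = out["ars_case"] - out["ars_control"]
    return out[["ars_case", "ars_control", "delta", "n_case", "n_control"]]


def screen_genes(
    table: pd.DataFrame,
    delta_min: float = 45.0,
    ars_min: float = 80.0,
) -> pd.DataFrame:
    """Threshold screen: keep genes with ``delta > delta_min`` and
    ``ars_case > ars_min``, ranked by ARS_case descending (delta breaks ties).
    """
    if table.empty:
        raise DataError("empty gene score table")
    hits = table[(table["delta"] > delta_min) & (table["ars_case"] > ars_min)]
    return hits.sort_values(["ars_case", "delta"], ascending=[False, False], kind="mergesort")


def rbe_curve(
    rm: RankMatrix,
    gene: str,
    bandwidth: float = 3.0,
) -> pd.DataFrame:
    """Rank-based expression (RBE) curve of one gene.

    For each condition, the empirical proportion of samples whose rank score
    falls at each integer score 1..100 (fractional tie-averaged scores are
    rounded to the nearest integer bin).  A right-shifted peak means high
    expression, a left-shifted one low expression.  Columns ``<cond>`` hold
    the raw proportions (summing to 1); ``<cond>_smooth`` hold a Gaussian-
    kernel smooth with standard deviation ``bandwidth`` rank units (omitted
    for conditions with fewer than 2 samples, with a warning).
    """
    if gene not in rm.values.index:
        raise DataError(f"gene {gene!r} not present")
    grid = np.arange(1, 101)
    out = pd.DataFrame(index=pd.Index(grid, name="rank_score"))
    for cond in pd.unique(rm.condition.dropna()):
        scores = rm.values.loc[gene, rm.samples_in(cond)].dropna().to_numpy()
        bins = np.clip(np.rint(scores).astype(int), 1, 100)
        counts = np.bincount(bins, minlength=101)[1:]
        if len(scores) == 0:
            continue
        props = counts / len(scores)
        out[cond] = props
        if len(scores) < 2:
            warnings.warn(
                f"condition {cond!r} has <2 samples; raw proportions only", stacklevel=2
            )
            continue
        if bandwidth and bandwidth > 0:
            out[f"{cond}_smooth"] = gaussian_filter1d(props, sigma=bandwidth, mode="constant")
    return out


def gpl_score(
    rm: RankMatrix,
    gene: str,
    condition: str,
    span: tuple[float, float] = (0.1, 0.9),
    min_samples: int = 10,
) -> float:
    """Plasticity score of a gene: spread of its rank-score distribution.

    The default formula is a documented heuristic — the width of the central
    80% of the gene's rank scores within ``condition`` (quantile ``span[1]``
    minus quantile ``span[0]``).  The published plasticity score comes from a
    companion method whose exact formula is not available, so values computed
    here are NOT comparable to published plasticity scores; only the ordering
    "constant gene = 0 < spread-out gene" is meaningful.  The quantile span
    is configurable.
    """
    if gene not in rm.values.index:
        raise DataError(f"gene {gene!r} not present")
    scores = rm.values.loc[gene, rm.samples_in(condition)].dropna().to_numpy()
    if len(scores) < min_samples:
        raise DataError(
            f"gpl_score needs >= {min_samples} samples in {condition!r}, got {len(scores)}"
        )
    lo, hi = span
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"invalid quantile span {span}")
    return float(np.quantile(scores, hi) - np.quantile(scores, lo))
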