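"""Diagnostic evaluation of a candidate transcript biomarker.

Given transcript levels in a case group (patients) and a control group
(normals), this module builds the ROC curve under the convention that higher
levels are more disease-like (a sample is called positive when its value is
at or above the cutoff), reports the AUC with a DeLong 95% CI, finds the
Youden-index optimal cutoff J = max(sensitivity + specificity - 1), and
offers the two dichotomization rules used downstream: a fixed cutoff
(over-expression rate) and a median split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DataError

__all__ = [
    "ROCResult",
    "roc_auc",
    "youden_cutoff",
    "overexpression_rate",
    "dichotomize_median",
]


@dataclass
class ROCResult:
    """ROC curve with AUC, DeLong CI and the Youden-optimal cutoff."""

    points: pd.DataFrame  # columns: cutoff, sensitivity, specificity
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float  # Youden-optimal
    j: float  # max(sens + spec - 1)


def _delong_ci(cases: np.ndarray, controls: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values; Wald CI clipped to [0,1]."""
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    rank_all = rankdata(combined)
    rank_cases = rankdata(cases)
    rank_controls = rankdata(controls)
    v10 = (rank_all[:m] - rank_cases) / n  # P(control < case_i), ties 1/2
    v01 = 1.0 - (rank_all[m:] - rank_controls) / m
    a = (rank_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(1 - alpha / 2)
    return (float(np.clip(a - z * se, 0, 1)), float(np.clip(a + z * se, 0, 1)))


def roc_auc(case_values, control_values) -> ROCResult:
    """ROC analysis of case vs. control values (positive: value >= cutoff).

    The AUC is the trapezoid-rule area, which for an ROC evaluated at every
    observed value equals the Mann-Whitney probability U/(n1*n2) with ties
    counted one half.  The 95% CI uses the DeLong method.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise DataError("both groups must be non-empty")
    if not (np.isfinite(cases).all() and np.isfinite(controls).all()):
        raise DataError("non-finite transcript levels")

    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    scores = np.concatenate([cases, controls])
    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))

    points = pd.DataFrame(
        {"cutoff": thresholds, "sensitivity": tpr, "specificity": 1.0 - fpr}
    )
    finite = points[np.isfinite(points["cutoff"])]
    js = finite["sensitivity"] + finite["specificity"] - 1.0
    jmax = float(js.max())
    # ties -> smallest cutoff attaining the maximum (thresholds are descending)
    tied = finite[js >= jmax - 1e-12]
    best_cutoff = float(tied["cutoff"].min())

    return ROCResult(
        points=points,
        auc=area,
        auc_ci=_delong_ci(cases, controls),
        cutoff=best_cutoff,
        j=jmax,
    )


def youden_cutoff(roc: ROCResult) -> float:
    """The cutoff maximizing J = sensitivity + specificity - 1 (smallest on ties)."""
    return roc.cutoff


@dataclass
class OverexpressionRate:
    fraction: float
    n_above: int
    n_total: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.n_above}/{self.n_total} ({100 * self.fraction:.0f}%)"


def overexpression_rate(values, cutoff: float) -> OverexpressionRate:
    """Fraction of values strictly above ``cutoff``, with the raw counts."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("empty input")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    n_above = int((v > cutoff).sum())
    return OverexpressionRate(fraction=n_above / v.size, n_above=n_above, n_total=v.size)


def dichotomize_median(values) -> pd.Series:
    """Split values at their median: > median -> "high", <= median -> "low".

    Ties at the median go to the low group, so n_low >= n_high.  Returns a
    Series of labels aligned with the input (index preserved for Series
    input).  A degenerate all-equal input yields an empty high group and a
    warning.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise DataError("need at least 2 values to dichotomize")
    med = float(s.median())
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")
    if (labels == "high").sum() == 0:
        warnings.warn("degenerate split: no values above the median", stacklevel=2)
    return labels
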