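"""Quantitative PCR math: relative (2^-ddCt) and standard-curve quantification.

``ddct`` implements the comparative-Ct method: dCt = Ct_target - Ct_reference
per sample (duplicate wells averaged at the Ct level first), ddCt relative to
the mean dCt of the calibrator samples (normal controls), relative expression
= 2^-ddCt.  ``std_curve`` fits the dilution-series line Ct ~ log10(quantity)
and reports the amplification efficiency E = 10^(-1/slope) - 1 (E = 1 for
perfect per-cycle doubling, slope -3.3219).  ``copy_ratio`` expresses an
absolute target copy number as a percentage of a reference gene's copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import DataError

__all__ = ["ddct", "StdCurve", "std_curve", "ct_to_quantity", "copy_ratio"]


def _validate_ct(values: pd.Series, what: str) -> None:
    v = values.to_numpy(dtype=float)
    if not np.isfinite(v).all() or (v <= 0).any():
        raise DataError(f"{what} Ct values must be finite and positive")


def ddct(records: pd.DataFrame) -> pd.DataFrame:
    """Relative expression by the comparative-Ct (2^-ddCt) method.

    ``records`` needs columns ``sample``, ``target_ct``, ``reference_ct`` and
    a boolean ``calibrator`` flag; several rows per sample (replicate wells)
    are averaged at the Ct level before dCt is formed.  The calibrator dCt is
    the mean dCt over all calibrator samples.

    Returns one row per sample with ``dct``, ``ddct`` and ``rel_expr``.
    """
    required = {"sample", "target_ct", "reference_ct", "calibrator"}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"Ct table lacks columns: {sorted(missing)}")
    _validate_ct(records["target_ct"], "target")
    _validate_ct(records["reference_ct"], "reference")

    per_sample = (
        records.groupby("sample", sort=False)
        .agg(
            target_ct=("target_ct", "mean"),
            reference_ct=("reference_ct", "mean"),
            calibrator=("calibrator", "any"),
        )
        .reset_index()
    )
    per_sample["dct"] = per_sample["target_ct"] - per_sample["reference_ct"]
    calib = per_sample.loc[per_sample["calibrator"], "dct"]
    if calib.empty:
        raise DataError("no calibrator samples flagged")
    per_sample["ddct"] = per_sample["dct"] - calib.mean()
    per_sample["rel_expr"] = 2.0 ** (-per_sample["ddct"])
    return per_sample


@dataclass(frozen=True)
class StdCurve:
    """Dilution-series standard curve Ct = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency E = 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def std_curve(log10_quantity, ct_values) -> StdCurve:
    """Least-squares standard curve from a serial dilution (>= 3 points)."""
    x = np.asarray(log10_quantity, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise DataError("standard curve needs >= 3 (log10 quantity, Ct) pairs")
    if np.ptp(x) == 0:
        raise DataError("dilution quantities have zero variance")
    fit = linregress(x, y)
    if fit.slope >= 0:
        raise DataError(f"standard-curve slope {fit.slope:.3f} is not negative")
    return StdCurve(slope=float(fit.slope), intercept=float(fit.intercept), r_squared=float(fit.rvalue**2))


def ct_to_quantity(curve: StdCurve, ct) -> np.ndarray:
    """Interpolate absolute quantities from Ct values via the standard curve."""
    ct = np.asarray(ct, dtype=float)
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def copy_ratio(copies_target, copies_reference) -> np.ndarray:
    """Target copies as a percentage of reference-gene copies."""
    tgt = np.asarray(copies_target, dtype=float)
    ref = np.asarray(copies_reference, dtype=float)
    if (ref <= 0).any():
        raise DataError("reference copies must be > 0")
    return 100.0 * tgt / ref
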