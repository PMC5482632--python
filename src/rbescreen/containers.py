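"""In-memory containers for expression data on the intensity and rank scales.

Both containers are thin wrappers around a pandas DataFrame (rows = probes or
genes, columns = samples) carrying two pieces of metadata the analysis needs:

* ``probe_to_gene`` — maps each row id to a gene symbol (identity mapping once
  probes have been collapsed to genes);
* ``condition`` — per-sample condition label (e.g. ``"ball"`` vs ``"bcell"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError


def _validate(values: pd.DataFrame, probe_to_gene: pd.Series, condition: pd.Series) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate row ids: {dups}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids: {dups}")
    missing = values.index.difference(probe_to_gene.index)
    if len(missing):
        raise DataError(f"rows absent from probe->gene map: {missing.tolist()[:5]}")
    missing = values.columns.difference(condition.index)
    if len(missing):
        raise DataError(f"samples without a condition label: {missing.tolist()[:5]}")


@dataclass
class ExpressionMatrix:
    """Probe/gene x sample intensity matrix with condition labels."""

    values: pd.DataFrame
    probe_to_gene: pd.Series
    condition: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_to_gene = self.probe_to_gene.reindex(self.values.index)
        self.condition = self.condition.reindex(self.values.columns)
        _validate(self.values, self.probe_to_gene, self.condition)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def samples_in(self, condition: str) -> pd.Index:
        cols = self.condition.index[self.condition == condition]
        if len(cols) == 0:
            raise DataError(f"no samples with condition {condition!r}")
        return cols


@dataclass
class RankMatrix(ExpressionMatrix):
    """Same axes as :class:`ExpressionMatrix`; entries are percentile rank
    scores on the 1..100 scale (possibly fractional where ties were averaged).
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy()
        finite = vals == vals  # NaN-safe mask
        if finite.any():
            lo, hi = vals[finite].min(), vals[finite].max()
            if lo < 1 or hi > 100:
                raise DataError(f"rank scores outside [1, 100]: min={lo}, max={hi}")
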