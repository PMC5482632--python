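"""Bundled reference tables.

``load_published_screen`` returns the published top-20 gene table from the
rank-based screen of B-cell ALL versus normal B-cell arrays: per gene, the
average rank score (ARS) in each condition, the printed delta, and the same
columns after the dataset update (``*_updated``), plus the chronic
lymphocytic leukemia ARS reported for contrast.  These printed summary
values are used as worked inputs for the delta/screen arithmetic; the
underlying subject-level data are not redistributable.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = ["load_published_screen"]


def load_published_screen() -> pd.DataFrame:
    path = files("rbescreen.data").joinpath("ball_top20_ars.tsv")
    with path.open("r") as fh:
        return pd.read_csv(fh, sep="\t", index_col="gene")
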