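import numpy as np
import pandas as pd
import pytest

from rbescreen import ExpressionMatrix, RankMatrix


def _build(cls, values: dict, conditions: dict, probe_to_gene: dict | None):
    df = pd.DataFrame(values)
    if probe_to_gene:
        df.index = list(probe_to_gene)
        p2g = pd.Series(probe_to_gene)
    else:
        p2g = pd.Series(df.index, index=df.index)
    return cls(values=df, probe_to_gene=p2g, condition=pd.Series(conditions, name="condition"))


def make_expression(values: dict, conditions: dict, probe_to_gene: dict | None = None):
    """Build a small ExpressionMatrix from plain dicts (columns = samples)."""
    return _build(ExpressionMatrix, values, conditions, probe_to_gene)


def make_rank(values: dict, conditions: dict, probe_to_gene: dict | None = None):
    return _build(RankMatrix, values, conditions, probe_to_gene)


def make_records(times, events, **covariates) -> pd.DataFrame:
    df = pd.DataFrame({"time": list(times), "event": list(events)})
    for name, vals in covariates.items():
        df[name] = list(vals)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20160601)
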