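import numpy as np
import pandas as pd
import pytest

from rbpflow import synthetic
from rbpflow.screening import ExpressionDataset


@pytest.fixture
def config():
    return synthetic.SimulationConfig(seed=1)


def make_dataset(values, groups=None, reference="reference", name="toy"):
    """Small helper: values is a dict gene -> list, first half reference."""
    df = pd.DataFrame(values).T
    n = df.shape[1]
    df.columns = [f"s{i}" for i in range(n)]
    if groups is None:
        half = n // 2
        groups = pd.Series(
            ["reference"] * half + ["case"] * (n - half), index=df.columns
        )
    return ExpressionDataset(df, groups, reference=reference, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
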