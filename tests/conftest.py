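import numpy as np
import pandas as pd
import pytest

from cocpipe import CountMatrix, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A light cohort configuration for fast generator tests."""
    return SimConfig(n_mice_per_condition=3, cocs_per_mouse=4, seed=1)


@pytest.fixture
def tiny_counts(rng):
    """Random 20-gene x 10-sample count matrix with lengths."""
    values = pd.DataFrame(
        rng.integers(0, 200, size=(20, 10)),
        index=[f"g{i:02d}" for i in range(20)],
        columns=[f"s{j}" for j in range(10)],
    )
    lengths = pd.Series(rng.integers(300, 5000, size=20), index=values.index)
    return CountMatrix(values, lengths)
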