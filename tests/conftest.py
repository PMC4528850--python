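import numpy as np
import pandas as pd
import pytest

from dendromass import TreeDataset, generate


@pytest.fixture
def tiny_df():
    """Three hand-written trees satisfying every record invariant."""
    return pd.DataFrame({
        "record_id": [0, 1, 2],
        "dbh": [5.0, 10.0, 15.0],
        "dm": [1.0, 1.8, 2.5],
        "ht": [4.0, 7.0, 9.0],
        "hc": [0.5, 2.0, 3.0],
        "da": [0.55, 0.60, 0.58],
        "db": [0.45, 0.50, 0.48],
        "w": [3.0, 15.0, 40.0],
    })


@pytest.fixture
def tiny_ds(tiny_df):
    return TreeDataset(records=tiny_df).validate()


@pytest.fixture(scope="session")
def ds50():
    """A 50-tree synthetic dataset shared across read-only tests."""
    return generate(n=50, seed=123)


@pytest.fixture(scope="session")
def ds180():
    return generate(n=180, seed=7)
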