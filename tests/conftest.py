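import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from scaledabund import (
    CountTable,
    InternalStandardSpec,
    relative_abundance,
    scaled_abundance,
)


@pytest.fixture
def toy_counts() -> CountTable:
    """Three samples, four taxa including the internal standard 'IS'."""
    df = pd.DataFrame(
        {
            "taxon_a": [300.0, 150.0, 600.0],
            "taxon_b": [500.0, 700.0, 200.0],
            "taxon_c": [100.0, 50.0, 100.0],
            "IS": [100.0, 100.0, 100.0],
        },
        index=["s1", "s2", "s3"],
    )
    return CountTable(df, mode="counts")


@pytest.fixture
def is_spec() -> InternalStandardSpec:
    return InternalStandardSpec("IS", 1000.0, units="copies/mcL")


@pytest.fixture
def toy_sa(toy_counts, is_spec):
    return scaled_abundance(relative_abundance(toy_counts), is_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
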