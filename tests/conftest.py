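import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pcirc import FixtureConfig, build_feature_table, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared across tests (read-only)."""
    return generate_dataset(FixtureConfig(n_pos=40, n_neg=40, seed=7))


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    ds = small_dataset
    return build_feature_table(ds.records, ds.genome, ds.junctions)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
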