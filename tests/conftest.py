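import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from mmgforce import SyntheticConfig, generate_dataset
from mmgforce.features import extract_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Two trials per level, enough for 96 windows; reused across tests."""
    cfg = SyntheticConfig()
    return generate_dataset(cfg, trials_per_level=2, seed=7)


@pytest.fixture(scope="session")
def small_feature_matrix(small_dataset):
    """Cheap (time + frequency) feature matrix of the small dataset."""
    return extract_dataset(
        small_dataset, groups=("time", "freq"), windows_per_level=None
    )
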