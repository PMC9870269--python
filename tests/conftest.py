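import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from frpsurv import (
    SyntheticFeatureConfig,
    TrainConfig,
    feature_to_frp,
    generate_features,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_feature_dataset():
    """Compact well-separated two-class feature set for fast pipeline tests."""
    cfg = SyntheticFeatureConfig(n_per_class=(8, 12), N=256, class_mean_shift=2.0,
                                 seed=7)
    return generate_features(cfg)


@pytest.fixture(scope="session")
def small_frps(small_feature_dataset):
    X, y = small_feature_dataset
    frps = [feature_to_frp(x) for x in X]
    return frps, y


@pytest.fixture(scope="session")
def fast_train_config():
    """Reduced-size LSTM settings for unit tests (not the pipeline defaults)."""
    return TrainConfig(hidden_size=16, max_epochs=300, seed=0)
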