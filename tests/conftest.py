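import numpy as np
import pytest

from tdgan import (GrudConfig, MaskedSeries, SyntheticConfig, UganConfig,
                   corrupt_dataset, generate_truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_series():
    """A hand-written 2-feature, 4-step record with a few missing cells."""
    values = np.array([[1.0, 0.0, 3.0, 4.0],
                       [5.0, 6.0, 0.0, 8.0]])
    mask = np.array([[1.0, 0.0, 1.0, 1.0],
                     [1.0, 1.0, 0.0, 1.0]])
    times = np.array([0.0, 1.0, 3.0, 6.0])
    return MaskedSeries(values, mask, times, ["hr", "map"])


@pytest.fixture(scope="session")
def small_benchmark():
    """A small correlated benchmark: truth, 30% MCAR corruption, held-out."""
    cfg = SyntheticConfig(d=3, n=40, records=8, seed=1024)
    truth = generate_truth(cfg)
    corrupted, heldout = corrupt_dataset(truth, 0.3, 77)
    return truth, corrupted, heldout


@pytest.fixture
def fast_configs():
    return (UganConfig(n_iter=60, batch_size=64, seed=5),
            GrudConfig(epochs=40, hidden_size=8, seed=5))


def random_masked_series(rng, d=3, n=12, p_miss=0.4):
    values = rng.normal(size=(d, n)) * 2 + 5
    mask = (rng.random((d, n)) >= p_miss).astype(float)
    times = np.cumsum(rng.uniform(0.5, 1.5, size=n))
    return MaskedSeries(values * mask, mask, times)
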