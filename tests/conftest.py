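import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_survival_data(rng, n, censoring=0.3):
    """Small random right-censored dataset for property tests."""
    durations = rng.exponential(5.0, size=n) + 0.05
    events = (rng.random(n) >= censoring).astype(int)
    return durations, events


@pytest.fixture
def make_survival_data(rng):
    def _make(n, censoring=0.3):
        return random_survival_data(rng, n, censoring)

    return _make
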