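import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eight_directions():
    return np.arange(0.0, 360.0, 45.0)


def gaussian_tuning(directions, b0, b1, b2):
    """Reference tuning curve on the circular difference (test oracle)."""
    d = (np.asarray(directions, dtype=float) - b1) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return b0 * np.exp(-((d / b2) ** 2))
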