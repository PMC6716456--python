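import numpy as np
import pytest

from ecnet.types import ROITimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_digraph_weights(rng: np.random.Generator, k: int, density: float = 0.7) -> np.ndarray:
    """Random nonnegative weight matrix with zero diagonal, max-normalized."""
    W = rng.uniform(0.05, 1.0, size=(k, k))
    W[rng.random((k, k)) > density] = 0.0
    np.fill_diagonal(W, 0.0)
    m = W.max()
    return W / m if m > 0 else W


def white_noise_ts(rng: np.random.Generator, T: int, k: int, tr: float = 1.0) -> ROITimeSeries:
    return ROITimeSeries(rng.normal(size=(T, k)), tr=tr)
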