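import numpy as np
import pytest

from bcmedia import MediaLandscape, ModelConfig, OpinionState, polarized_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def no_media():
    return MediaLandscape(())


@pytest.fixture
def homophilous_fixture():
    """Two disconnected communities with well-separated opinion means."""
    return polarized_network(
        100, intra_p=0.2, inter_p=0.0, means=(0.28, 0.87), spread=0.05,
        rng=np.random.default_rng(7),
    )


def naive_dw_step(x: np.ndarray, epsilon: float, mu: float, rng: np.random.Generator) -> None:
    """Independent textbook implementation of one bounded-confidence pair event
    with uniform partner choice; mutates ``x``. Consumes the random stream as
    (agent draw, skip-self peer draw)."""
    n = x.size
    i = int(rng.integers(n))
    k = int(rng.integers(n - 1))
    j = k if k < i else k + 1
    if abs(x[i] - x[j]) <= epsilon:
        xi, xj = x[i], x[j]
        x[i] = xi + mu * (xj - xi)
        x[j] = xj + mu * (xi - xj)
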