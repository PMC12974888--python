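import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, dim=8, cond=4.0):
    """Well-conditioned random SPD matrix."""
    A = rng.standard_normal((dim, dim))
    Q, _ = np.linalg.qr(A)
    w = np.exp(rng.uniform(-np.log(cond) / 2, np.log(cond) / 2, size=dim))
    return (Q * w) @ Q.T


def random_symmetric(rng, dim=8, scale=1.0):
    A = rng.standard_normal((dim, dim))
    return scale * (A + A.T) / 2


@pytest.fixture
def spd_pair(rng):
    return random_spd(rng), random_spd(rng)
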