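import numpy as np
import pytest

from eplsa import MEMParams


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture
def small_params(rng):
    """Generic pairwise model with entries in (-0.5, 0.5), N=4."""
    n = 4
    h = rng.uniform(-0.5, 0.5, n)
    j = rng.uniform(-0.5, 0.5, (n, n))
    j = (j + j.T) / 2
    np.fill_diagonal(j, 0.0)
    return MEMParams(h=h, J=j)


def make_params(n: int, rng: np.random.Generator, scale: float = 0.5) -> MEMParams:
    h = rng.uniform(-scale, scale, n)
    j = rng.uniform(-scale, scale, (n, n))
    j = (j + j.T) / 2
    np.fill_diagonal(j, 0.0)
    return MEMParams(h=h, J=j)
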