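import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n, rng, density=0.5):
    """Random symmetric non-negative matrix with zero diagonal."""
    a = rng.random((n, n)) * (rng.random((n, n)) < density)
    a = np.triu(a, 1)
    return a + a.T


def planted_two_block(
    n, seed, p_in=0.3, p_out=0.05, mean_in=2.0, mean_out=0.5, sd=0.1
):
    """Two equal planted blocks with distinct densities and edge-weight means."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([1, 2], [n // 2, n - n // 2])
    iu, ju = np.triu_indices(n, 1)
    same = labels[iu] == labels[ju]
    edge = np.where(same, rng.random(len(iu)) < p_in, rng.random(len(iu)) < p_out)
    wts = np.abs(
        np.where(same, rng.normal(mean_in, sd, len(iu)), rng.normal(mean_out, sd, len(iu)))
    )
    a = np.zeros((n, n))
    a[iu, ju] = edge * wts
    return a + a.T, labels
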