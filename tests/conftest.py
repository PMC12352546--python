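import numpy as np
import pytest

from prominet import ConnectomeMatrix, Partition


def toy_values():
    """6-node two-block toy FC: 0.8 triangle in block 1, 0.6 within block 2,
    0.2 bridging between blocks."""
    a = np.zeros((6, 6))
    for i, j, w in [(0, 1, 0.8), (0, 2, 0.8), (1, 2, 0.8), (3, 4, 0.6), (2, 3, 0.2)]:
        a[i, j] = a[j, i] = w
    return a


@pytest.fixture
def toy_fc():
    return ConnectomeMatrix(toy_values(), label="toy")


@pytest.fixture
def toy_partition():
    return Partition([1, 1, 1, 2, 2, 2])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_connectome(rng, n, label="rand"):
    a = rng.uniform(-1, 1, size=(n, n))
    a = np.triu(a, k=1)
    a = a + a.T
    return ConnectomeMatrix(a, label=label)


def random_partition(rng, n, k):
    """A random partition of n nodes into exactly k non-empty communities."""
    sigma = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, size=n - k)])
    return Partition.from_labels(rng.permutation(sigma))
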