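import numpy as np
import pytest

from sdtp.netprep import MultilayerTensor, WeightedNetwork


@pytest.fixture
def triangle_net() -> WeightedNetwork:
    """Triangle over genes a, b, c with weights 0.2, 0.3, 0.5."""
    return WeightedNetwork.from_edges(
        [("a", "b", 0.2), ("b", "c", 0.3), ("a", "c", 0.5)]
    )


@pytest.fixture
def small_tensor() -> MultilayerTensor:
    """3 genes x 2 layers: a unit-weight clique in both layers."""
    n, m = 3, 2
    W = np.ones((n, n, m))
    for k in range(m):
        np.fill_diagonal(W[:, :, k], 0.0)
    return MultilayerTensor(["a", "b", "c"], ["L0", "L1"], W)


def random_dense_tensor(seed: int) -> MultilayerTensor:
    """Dense random tensor with i.i.d. uniform(0, 1) weights, n <= 8, m <= 3."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    m = int(rng.integers(1, 4))
    W = np.zeros((n, n, m))
    iu = np.triu_indices(n, k=1)
    for k in range(m):
        w = rng.uniform(0, 1, size=len(iu[0]))
        mat = np.zeros((n, n))
        mat[iu] = w
        W[:, :, k] = mat + mat.T
    return MultilayerTensor(
        [f"g{i}" for i in range(n)], [f"L{k}" for k in range(m)], W
    )
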