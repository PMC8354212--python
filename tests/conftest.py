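import numpy as np
import pytest

from rfcell.datamodel import ExpressionMatrix


@pytest.fixture
def small_matrix():
    """3 cells x 2 genes toy matrix."""
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        ["c1", "c2", "c3"],
        ["g1", "g2"],
        unit="TPM",
    )


def random_partition_pair(rng, m_max=30):
    """A random pair of partitions of the same items, for metric oracles."""
    m = rng.integers(2, m_max + 1)
    k1 = rng.integers(1, min(m, 6) + 1)
    k2 = rng.integers(1, min(m, 6) + 1)
    return rng.integers(0, k1, m), rng.integers(0, k2, m)


def marker_sparse_dataset(seed=1, m=200, n_inf=50, n_noise=950, n_clusters=3):
    """Marker-style sparse data: informative genes are expressed in one
    cluster and mostly zero elsewhere, so the cluster signal lives in the
    zero/nonzero pattern as it does in real scRNA-seq marker genes."""
    rng = np.random.default_rng(seed)
    assign = rng.integers(0, n_clusters, m)
    vals = np.zeros((m, n_inf + n_noise))
    on_cluster = rng.integers(0, n_clusters, n_inf)
    for j in range(n_inf):
        on = assign == on_cluster[j]
        expr = np.exp(rng.normal(3.0, 1.0, m))
        drop = np.where(on, 0.2, 0.95)
        vals[:, j] = np.where(rng.random(m) < drop, 0.0, expr)
    for j in range(n_inf, n_inf + n_noise):
        expr = np.exp(rng.normal(2.0, 1.0, m))
        vals[:, j] = np.where(rng.random(m) < 0.8, 0.0, expr)
    x = ExpressionMatrix(
        vals,
        [f"c{i:04d}" for i in range(m)],
        [f"g{j:04d}" for j in range(n_inf + n_noise)],
        unit="synthetic-marker",
    )
    mask = np.zeros(n_inf + n_noise, dtype=bool)
    mask[:n_inf] = True
    labels = np.array([f"k{a}" for a in assign], dtype=object)
    return x, labels, mask
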