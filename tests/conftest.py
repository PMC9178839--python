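import numpy as np
import pytest

from firthgee import ClusteredDataset


def make_clustered(
    rng,
    n_clusters=12,
    size_range=(2, 5),
    p=2,
    beta=None,
    within_corr=0.5,
    weights=None,
):
    """Small correlated clustered binary dataset for unit tests."""
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_clusters)
    n = int(sizes.sum())
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    if beta is None:
        beta = np.concatenate([[-0.3], 0.6 * np.ones(p)])
    pi = 1.0 / (1.0 + np.exp(-(X @ beta)))
    a = np.repeat(rng.standard_normal(n_clusters), sizes)
    z = np.sqrt(within_corr) * a + np.sqrt(1 - within_corr) * rng.standard_normal(n)
    from scipy.stats import norm

    y = (norm.cdf(z) < pi).astype(float)
    ids = np.repeat(np.arange(n_clusters), sizes)
    return ClusteredDataset(cluster_ids=ids, y=y, X=X, weights=weights)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_data(rng):
    """A well-behaved (non-separated) clustered dataset."""
    return make_clustered(rng, n_clusters=15, size_range=(2, 5), p=2)


@pytest.fixture
def separated_data():
    """Quasi-separated clustered dataset: one binary covariate level has no
    events at all."""
    rng = np.random.default_rng(7)
    n_clusters, size = 12, 4
    n = n_clusters * size
    rare = np.repeat((np.arange(n_clusters) < 3).astype(float), size)
    x2 = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), rare, x2])
    pi = 1.0 / (1.0 + np.exp(-(-1.0 + 0.3 * x2)))
    y = (rng.random(n) < pi).astype(float)
    y[rare == 1.0] = 0.0
    ids = np.repeat(np.arange(n_clusters), size)
    return ClusteredDataset(cluster_ids=ids, y=y, X=X)
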