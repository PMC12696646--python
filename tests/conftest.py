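import numpy as np
import pytest
import scipy.sparse as sp

from guidedcoc import CellFeatureMatrix, ClusterAssignment, normalize_joint


def random_joint(rng, n, q, sparse=False, zero_frac=0.0):
    """Seeded random joint distribution from Poisson counts (all rows/cols
    guaranteed positive mass by adding a diagonal-ish floor)."""
    M = rng.poisson(4, size=(n, q)).astype(float)
    if zero_frac:
        M[rng.random(M.shape) < zero_frac] = 0.0
    M[np.arange(n), np.arange(n) % q] += 1.0  # no zero rows/cols
    M[np.arange(q) % n, np.arange(q)] += 1.0
    vals = sp.csr_matrix(M) if sparse else M
    return normalize_joint(CellFeatureMatrix(vals))


def random_clusters(rng, m, c):
    """Seeded random assignment with every cluster non-empty."""
    labels = rng.integers(0, c, size=m)
    labels[rng.permutation(m)[:c]] = np.arange(c)
    return ClusterAssignment(labels, c)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def small_triple():
    """A well-separated tiny planted triple for optimizer tests."""
    from guidedcoc import SyntheticSpec, default_block_means, generate

    spec = SyntheticSpec(
        n_source=60, n_target=80, q=48, n_source_clusters=3, n_target_clusters=3,
        k_features=3, dropout=0.0, atac_distortion=0.0, seed=7,
        block_means=default_block_means(3, 3, base=1.0, contrast=6.0),
    )
    return generate(spec)
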