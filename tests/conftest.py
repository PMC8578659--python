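import numpy as np
import pytest

from hicarch.matrix import ContactMatrix


def random_raw_matrix(n, seed, low=1, high=50, chrom="chrT", bin_size=40_000):
    """Dense positive random count matrix (no zero marginals)."""
    rng = np.random.default_rng(seed)
    u = rng.integers(low, high, size=(n, n))
    v = np.triu(u) + np.triu(u, 1).T
    return ContactMatrix(chrom, bin_size, v.astype(float), kind="raw")


def random_oe_matrix(n, seed, chrom="chrT", bin_size=40_000):
    """Symmetric positive matrix tagged as O/E for transform-level tests."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.2, 3.0, size=(n, n))
    v = (np.triu(u) + np.triu(u, 1).T)
    return ContactMatrix(chrom, bin_size, v, kind="oe")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
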