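import numpy as np
import pytest

from tadscan.glr import default_null_table, simulate_null
from tadscan.hic_io import ContactMap


@pytest.fixture(scope="session")
def small_table():
    """Cheap Monte-Carlo null table for unit tests of the pipeline."""
    return simulate_null(delta=0.02, grid_n=100, n_samples=2000, seed=7)


@pytest.fixture(scope="session")
def full_table():
    """The default (process-cached) null table used for real detection."""
    return default_null_table()


def random_contact_map(rng, n, density=0.6, scale=10.0):
    """Small random symmetric map for oracle comparisons."""
    x = rng.random((n, n)) * scale
    x[rng.random((n, n)) > density] = 0.0
    x = np.triu(x)
    i, j = np.nonzero(x)
    return ContactMap.from_coo(i, j, x[i, j], resolution=1, chrom="t", n_bins=n)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def three_block_matrix(weak_middle=True, n=30, seed=77):
    """Three equal blocks with a strong first boundary at n/3.

    With ``weak_middle`` the second and third blocks share their mean with
    the rectangle between them, so the boundary at 2n/3 separates nothing:
    it is a null (weak) boundary.  Otherwise all three blocks stand out
    against a zero background and both boundaries are strong.
    """
    rng = np.random.default_rng(seed)
    t1, t2 = n // 3, 2 * n // 3
    mean = np.zeros((n, n))
    mean[:t1, :t1] = 200.0
    mean[t1:, t1:] = 50.0 if weak_middle else 0.0
    mean[t1:t2, t1:t2] = 50.0 if weak_middle else 120.0
    mean[t2:, t2:] = 50.0
    x = np.triu(rng.normal(mean, 5.0))
    x = np.where(mean == 0.0, np.maximum(x, 0.0), x)   # background is a count
    i, j = np.nonzero(x)
    cm = ContactMap.from_coo(i, j, x[i, j], resolution=1, chrom="t", n_bins=n)
    return cm, [t1, t2]
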