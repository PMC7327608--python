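import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cardioknn import LabeledDataset, MaskedMatrix, gen_uci_like

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def uci_like():
    return gen_uci_like(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def masked_from_lists(values, mask):
    return MaskedMatrix(np.asarray(values, dtype=float), np.asarray(mask))


@pytest.fixture
def small_masked():
    """[[1, ?], [3, 4]] -- the smallest interesting incomplete matrix."""
    return masked_from_lists([[1.0, 0.0], [3.0, 4.0]], [[1, 0], [1, 1]])


def balanced_rank1_design(n_rows=120, d=10):
    """Exact rank-1 data with a balanced co-observation mask.

    Row j has coefficient a_j (from a sign- and magnitude-balanced cycle)
    times the uniform unit vector v, and masks exactly one cell, cycling
    through the columns.  Every column then has the same observation count,
    every column pair the same co-observation count, and the group sums of
    a_j and a_j^2 vanish/coincide, so the masked scatter matrix is exactly
    (const) * v v' + (const) * I and its top eigenvector is exactly v: the
    one configuration in which masked-PCA recovery of rank-1 data is exact
    rather than approximate.
    """
    assert n_rows % (4 * d) == 0
    v = np.ones(d) / np.sqrt(d)
    pattern = np.array([1.0, -1.0, 2.0, -2.0])
    coeffs = np.empty(n_rows)
    mask = np.ones((n_rows, d), dtype=np.uint8)
    per_col = n_rows // d
    for j in range(n_rows):
        col = j % d
        rank_in_group = j // d
        coeffs[j] = pattern[rank_in_group % 4]
        mask[j, col] = 0
    truth = coeffs[:, None] * v[None, :]
    assert per_col % 4 == 0
    return MaskedMatrix(truth * mask, mask), truth
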