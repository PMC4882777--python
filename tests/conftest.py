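import numpy as np
import pandas as pd
import pytest

from arborhic.bins_io import BIN_COLUMNS, BinTable, ContactMatrix, make_bins


@pytest.fixture
def bins5():
    """Five 1-Mbp bins on one chromosome."""
    return make_bins({"chr1": 5_000_000}, 1_000_000)


@pytest.fixture
def bins_two_chrom():
    """Two chromosomes with 3 + 2 bins."""
    return make_bins({"chr1": 3_000_000, "chr2": 2_000_000}, 1_000_000)


@pytest.fixture
def toy_matrix(bins5):
    """Symmetric 5x5 integer count matrix."""
    rng = np.random.default_rng(42)
    upper = rng.integers(1, 20, size=(5, 5))
    counts = np.triu(upper) + np.triu(upper, 1).T
    return ContactMatrix(bins5, counts.astype(float))


def random_symmetric(n, rng, low=0.0, high=10.0):
    upper = rng.uniform(low, high, size=(n, n))
    return np.triu(upper) + np.triu(upper, 1).T


@pytest.fixture
def rng():
    return np.random.default_rng(0)
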