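import numpy as np
import pytest

from rablmap import ContactMatrix, bin_genome, demo_genome


@pytest.fixture
def demo_bt():
    return bin_genome(demo_genome(), 1_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_matrix(demo_bt, rng):
    """A sparse random raw count matrix over the demo genome."""
    n = demo_bt.nbins
    k = 30_000
    i = rng.integers(0, n, size=k)
    j = rng.integers(0, n, size=k)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    key = lo * n + hi
    uniq = np.unique(key)
    lo, hi = uniq // n, uniq % n
    val = rng.poisson(5.0, size=uniq.size) + 1
    return ContactMatrix.from_entries(demo_bt, lo, hi, val.astype(float))


def dense_single_chrom(n=40, binsize=1_000, fill=None, name="chrZ"):
    """One-chromosome ContactMatrix from a dense symmetric array (or zeros)."""
    from rablmap.genome import BinTable, GenomeModel

    genome = GenomeModel(((name, n * binsize),), {name: n * binsize // 2})
    bt = BinTable(genome, binsize)
    dense = np.zeros((n, n)) if fill is None else np.asarray(fill, dtype=float)
    return ContactMatrix.from_dense(bt, dense)
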