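import numpy as np
import pytest

from rablmap import (
    contact_probability,
    cp_log2_ratio,
    demo_genome,
    log2_ratio_map,
    svl_ratio,
    saccer3_genome,
    virtual_4c,
)
from rablmap import bin_genome, demo_config, simulate_pair
from rablmap.compare import default_strata_edges

from conftest import dense_single_chrom


def test_log2_ratio_of_matrix_with_itself_is_zero(random_matrix):
    maps = log2_ratio_map(random_matrix, random_matrix)
    for chrom, block in maps.items():
        finite = np.isfinite(block)
        assert np.all(block[finite] == 0.0)
        # both-zero cells are NaN, not 0
        assert np.isnan(block[~finite]).all()


def test_log2_ratio_antisymmetric(random_matrix, rng):
    other = random_matrix.copy()
    other.val = other.val + rng.integers(0, 3, size=other.val.size)
    ab = log2_ratio_map(random_matrix, other, eps=1.0)
    ba = log2_ratio_map(other, random_matrix, eps=1.0)
    for chrom in ab:
        a, b = ab[chrom], ba[chrom]
        ok = np.isfinite(a)
        assert np.allclose(a[ok], -b[ok])


def test_log2_ratio_requires_shared_binning(random_matrix):
    coarse = dense_single_chrom(n=10, binsize=2_000)
    with pytest.raises(ValueError):
        log2_ratio_map(random_matrix, coarse)


def test_contact_probability_strata():
    n = 60
    dense = np.zeros((n, n))
    # value k at every pair of lag k, for k = 1..10
    for k in range(1, 11):
        idx = np.arange(n - k)
        dense[idx, idx + k] = float(k)
        dense[idx + k, idx] = float(k)
    m = dense_single_chrom(n=n, fill=dense)
    prof = contact_probability(m, chrom="chrZ")
    # linear strata out to 50 kb: stratum at distance k*1000 has mean k
    for k in range(1, 11):
        i = int(np.where(prof.distances == k * 1000)[0][0])
        assert prof.values[i] == pytest.approx(k)
        assert prof.n_pairs[i] == n - k
    # beyond lag 10 everything is zero
    assert np.all(prof.values[prof.distances > 10_000] == 0.0)
    # probability mode sums to 1
    p = contact_probability(m, chrom="chrZ", mode="probability")
    assert p.values.sum() == pytest.approx(1.0)


def test_cp_ratio_recovers_planted_band_fold():
    n = 120
    base = np.zeros((n, n))
    for k in range(1, n):
        idx = np.arange(n - k)
        base[idx, idx + k] = 100.0 / k
    base = base + base.T
    boosted = base.copy()
    for k in range(20, 41):  # 20-40 kb band boosted 1.3-fold
        idx = np.arange(n - k)
        boosted[idx, idx + k] *= 1.3
        boosted[idx + k, idx] = boosted[idx, idx + k]
    con = dense_single_chrom(n=n, binsize=1_000, fill=base, name="chrZ")
    iaa = dense_single_chrom(n=n, binsize=1_000, fill=boosted, name="chrZ")
    edges = default_strata_edges(n - 1, 1_000)
    pc = contact_probability(con, chrom="chrZ", strata_edges=edges)
    pi = contact_probability(iaa, chrom="chrZ", strata_edges=edges)
    df = cp_log2_ratio(pi, pc)
    inside = df[(df["distance"] >= 20_000) & (df["distance"] < 40_000)]
    outside = df[df["distance"] < 15_000]
    assert np.allclose(inside["log2_ratio"], np.log2(1.3), atol=1e-9)
    assert np.allclose(outside["log2_ratio"], 0.0, atol=1e-9)


def test_cp_ratio_requires_matching_strata(random_matrix):
    p1 = contact_probability(random_matrix)
    p2 = contact_probability(random_matrix, linear_to=10_000)
    with pytest.raises(ValueError):
        cp_log2_ratio(p1, p2)


def test_svl_has_one_value_per_chromosome_sixteen_for_saccer3():
    from rablmap import ContactMatrix

    bt = bin_genome(saccer3_genome(), 10_000)
    rng = np.random.default_rng(0)
    k = 40_000
    row = rng.integers(0, bt.nbins, size=k)
    col = rng.integers(0, bt.nbins, size=k)
    row, col = np.minimum(row, col), np.maximum(row, col)
    uniq = {(int(i), int(j)): 1.0 for i, j in zip(row, col)}
    r = np.array([a for a, _ in uniq]); c = np.array([b for _, b in uniq])
    m = ContactMatrix(bt, r, c, np.ones(r.size))
    res = svl_ratio(m, L=100_000)
    assert len(res.table) == 16
    assert len(res.ratios) == 16
    assert list(res.table["chrom"]) == bt.chrom_names


def test_svl_rescale_invariant_and_threshold_edges():
    n = 300  # 300 kb chromosome at 1 kb
    dense = np.zeros((n, n))
    rng = np.random.default_rng(3)
    iu = np.triu_indices(n, k=1)
    dense[iu] = rng.poisson(2.0, size=iu[0].size)
    dense = dense + dense.T
    m = dense_single_chrom(n=n, fill=dense)
    res = svl_ratio(m, L=100_000)
    scaled = m.copy()
    scaled.val = scaled.val * 7.25
    res2 = svl_ratio(scaled, L=100_000)
    assert res2.ratios[0] == pytest.approx(res.ratios[0], rel=1e-12)
    # a pair at exactly L counts as long
    only_L = np.zeros((n, n))
    only_L[0, 100] = only_L[100, 0] = 5.0
    mL = dense_single_chrom(n=n, fill=only_L)
    tab = svl_ratio(mL, L=100_000).table
    assert tab.loc[0, "long_sum"] == 5.0 and tab.loc[0, "short_sum"] == 0.0


def test_svl_short_chromosome_warns_nan():
    m = dense_single_chrom(n=40)  # 40 kb < L
    with pytest.warns(UserWarning, match="shorter than L"):
        res = svl_ratio(m, L=100_000)
    assert np.isnan(res.ratios[0])


def test_virtual_4c_peaks_at_pericentromere():
    con, _, _ = simulate_pair(demo_config(), seed=11)
    genome = con.bins.genome
    chrom = genome.names[0]
    prof = virtual_4c(con, chrom)
    cen = genome.centromere(chrom)
    near = prof[(prof["start"] - cen).abs() < 10_000]["value"]
    far = prof[(prof["start"] - cen).abs() > 40_000]["value"]
    assert near.mean() > 1.5 * np.median(far)
    assert len(prof) == con.bins.chrom_nbins(chrom)
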