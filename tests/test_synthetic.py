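import numpy as np
import pytest

from rablmap import (
    ConditionEffects,
    PlantedLoop,
    car_like_loops,
    contact_probability,
    default_config,
    demo_config,
    expected_matrix,
    expected_rate,
    recover_alpha,
    saccer3_genome,
    simulate_pair,
)
from rablmap.synthetic import inter_rate_block, intra_rate_block


def test_intra_rate_closed_form_far_from_features():
    cfg = demo_config()
    lam = intra_rate_block(cfg, "chrA")
    # pick bins far from the centromere (no loops configured): pure decay
    i, j = 150, 170
    s = abs(j - i) * cfg.binsize
    pure = cfg.c_intra * (s + cfg.s0) ** (-cfg.alpha)
    assert lam[i, j] == pytest.approx(pure, rel=1e-3)
    # symmetric
    assert np.allclose(lam, lam.T)


def test_inter_rate_closed_form():
    cfg = demo_config()
    g = cfg.genome
    lam = inter_rate_block(cfg, g.names[0], g.names[1])
    bt = cfg.bin_table()
    c1 = bt.locate(g.names[0], g.centromere(g.names[0])) - bt.chrom_offset(g.names[0])
    c2 = bt.locate(g.names[1], g.centromere(g.names[1])) - bt.chrom_offset(g.names[1])
    # centromere-proximal cell approaches c_inter * kappa, far corner c_inter
    assert lam[c1, c2] == pytest.approx(cfg.c_inter * cfg.kappa, rel=0.01)
    assert lam[-1, -1] == pytest.approx(cfg.c_inter, rel=1e-6)
    # expected_rate agrees with the block on global indices
    i = bt.chrom_offset(g.names[0]) + c1
    j = bt.chrom_offset(g.names[1]) + c2
    assert expected_rate(cfg, i, j) == pytest.approx(lam[c1, c2])


def test_depleted_condition_effects_are_multiplicative():
    lp = PlantedLoop("chrA", 60_000, 70_000, strength=3.0, fold=1.6,
                     fold_halfwidth=8_000.0)
    cfg = demo_config(loops=(lp,),
                      effects=ConditionEffects(
                          decay_band_folds=((20_000, 40_000, 0.8),),
                          kappa_fold=0.5))
    con = intra_rate_block(cfg, "chrA", "control")
    dep = intra_rate_block(cfg, "chrA", "depleted")
    ratio = dep / con
    bt = cfg.bin_table()
    b1 = bt.locate("chrA", 60_500) - bt.chrom_offset("chrA")
    b2 = bt.locate("chrA", 70_500) - bt.chrom_offset("chrA")
    assert ratio[b1, b2] == pytest.approx(1.6)
    # decay band fold applies at 30 kb separation away from the loop box
    assert ratio[150, 180] == pytest.approx(0.8)
    # untouched cells unchanged
    assert ratio[150, 160] == pytest.approx(1.0)
    # kappa fold halves the clustering amplitude of the inter block
    g = cfg.genome
    icon = inter_rate_block(cfg, g.names[0], g.names[1], "control")
    idep = inter_rate_block(cfg, g.names[0], g.names[1], "depleted")
    c1 = bt.locate(g.names[0], g.centromere(g.names[0])) - bt.chrom_offset(g.names[0])
    c2 = bt.locate(g.names[1], g.centromere(g.names[1])) - bt.chrom_offset(g.names[1])
    expect = (1 + (cfg.kappa * 0.5 - 1)) / (1 + (cfg.kappa - 1))
    assert idep[c1, c2] / icon[c1, c2] == pytest.approx(expect, rel=0.01)


def test_simulate_pair_bit_identical_for_same_seed():
    cfg = demo_config(depth=5e5)
    con1, iaa1, t1 = simulate_pair(cfg, seed=9)
    con2, iaa2, t2 = simulate_pair(cfg, seed=9)
    for a, b in ((con1, con2), (iaa1, iaa2)):
        assert np.array_equal(a.row, b.row)
        assert np.array_equal(a.col, b.col)
        assert np.array_equal(a.val, b.val)
    assert t1.realized_totals == t2.realized_totals
    con3, _, _ = simulate_pair(cfg, seed=10)
    assert not (con3.val.size == con1.val.size
                and np.array_equal(con3.val, con1.val))


def test_conditions_use_independent_streams():
    # the control draw must not depend on depleted-condition parameters
    cfg_a = demo_config(depth=5e5)
    cfg_b = demo_config(depth=5e5,
                        effects=ConditionEffects(kappa_fold=0.5))
    con_a, _, _ = simulate_pair(cfg_a, seed=3)
    con_b, _, _ = simulate_pair(cfg_b, seed=3)
    assert np.array_equal(con_a.val, con_b.val)


def test_expected_depth_is_respected():
    cfg = demo_config(depth=5e5)
    totals = []
    for seed in range(5):
        con, iaa, truth = simulate_pair(cfg, seed=seed)
        totals += [con.total, iaa.total]
        assert truth.scales["control"] * truth.expected_totals["control"] == \
            pytest.approx(cfg.depth)
    # realized totals are Poisson around the depth: within ~5 sigma
    totals = np.asarray(totals, dtype=float)
    assert np.all(np.abs(totals - cfg.depth) < 5 * np.sqrt(cfg.depth))


def test_recover_alpha_pure_decay_noiseless():
    cfg = default_config(peri_amp=1.0, kappa=1.0)  # decay only
    exp = expected_matrix(cfg, scope="intra")
    prof = contact_probability(exp)
    alpha_hat = recover_alpha(prof, s0=cfg.s0)
    assert abs(alpha_hat - cfg.alpha) < 0.02


def test_recover_alpha_flat_when_alpha_zero():
    cfg = demo_config(alpha=0.0, peri_amp=1.0, kappa=1.0)
    exp = expected_matrix(cfg, scope="intra")
    prof = contact_probability(exp)
    assert abs(recover_alpha(prof, s0=cfg.s0)) < 0.05


def test_car_like_loops_deterministic_and_valid():
    g = saccer3_genome()
    loops1 = car_like_loops(g, n=20, fold=1.6)
    loops2 = car_like_loops(g, n=20, fold=1.6)
    assert loops1 == loops2
    assert len(loops1) == 20
    dists = {lp.anchor2 - lp.anchor1 for lp in loops1}
    assert dists <= {8_000, 10_000, 12_000}
    for lp in loops1:
        assert 0 <= lp.anchor1 < lp.anchor2 < g.length(lp.chrom)
        assert lp.fold == 1.6
    with pytest.raises(ValueError):
        car_like_loops(g, n=1_000)


def test_config_validation():
    with pytest.raises(ValueError):
        demo_config(kappa=0.5)
    with pytest.raises(ValueError):
        demo_config(alpha=-1.0)
    with pytest.raises(ValueError):
        demo_config(loops=(PlantedLoop("chrNope", 1_000, 2_000),))
    with pytest.raises(ValueError):
        PlantedLoop("chrA", 5_000, 4_000)
    with pytest.raises(ValueError):
        PlantedLoop("chrA", 1_000, 2_000, strength=0.5)
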