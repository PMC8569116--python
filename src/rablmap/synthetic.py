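"""Synthetic paired (control, depleted) Rabl-configuration Hi-C generator.

The expected contact rate is a product of multiplicative features on top of a
power-law intra-chromosomal distance decay and a flat inter-chromosomal
background:

* intra:  lambda = c_intra * (s + s0)^(-alpha) * peri-centromeric factor
  * planted-loop factors, with s the genomic separation in bp;
* inter:  lambda = c_inter * (1 + (kappa - 1) * g(d1) * g(d2)) where g is a
  Gaussian of width sigma_cen in the distance of each bin from its centromere
  (centromere clustering, the Rabl hallmark).

The depleted condition applies per-feature multiplicative fold changes only:
distance-band folds on the decay, a fold on the centromere-clustering
amplitude kappa, and per-loop folds (modeled as a uniform rate change in an
upper-triangle box around the loop anchor so the planted fold is exactly the
quantity a box-mean quantification recovers).  Counts are independent Poisson
draws per upper-triangle cell, with rates scaled so the expected total equals
the configured sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .compare import DistanceDecayProfile
from .genome import BinTable, GenomeModel, demo_genome, saccer3_genome
from .matrix import ContactMatrix

__all__ = [
    "PlantedLoop",
    "ConditionEffects",
    "SyntheticConfig",
    "SyntheticTruth",
    "expected_rate",
    "expected_matrix",
    "simulate_pair",
    "recover_alpha",
    "car_like_loops",
    "default_config",
    "demo_config",
]

CONDITIONS = ("control", "depleted")


@dataclass(frozen=True)
class PlantedLoop:
    """A planted CAR-like loop between two intra-chromosomal anchors.

    ``strength`` is the multiplicative contact enrichment at the loop center
    (Gaussian footprint of width ``sigma`` bp in both axes); ``fold`` is the
    depleted-condition rate change applied uniformly inside the
    ``fold_halfwidth`` upper-triangle box around the anchor.
    """

    chrom: str
    anchor1: int
    anchor2: int
    strength: float = 3.0
    sigma: float = 2_000.0
    fold: float = 1.0
    fold_halfwidth: float = 8_000.0

    def __post_init__(self):
        if self.anchor2 <= self.anchor1:
            raise ValueError("anchor2 must exceed anchor1")
        if self.strength < 1:
            raise ValueError("loop strength must be >= 1")


@dataclass(frozen=True)
class ConditionEffects:
    """Depleted-condition fold changes, each tied to one generative feature."""

    decay_band_folds: tuple[tuple[int, int, float], ...] = ()  # (s_lo, s_hi, fold) bp
    kappa_fold: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    genome: GenomeModel
    binsize: int = 1_000
    alpha: float = 1.5
    s0: float = 1_000.0           # decay offset (bp), regularizes s -> 0
    c_intra: float = 1.0
    # c_inter below yields ~38% inter-chromosomal contacts on the default
    # sacCer3 model, typical of Rabl-configured yeast libraries.
    c_inter: float = 8.5e-9
    kappa: float = 4.0            # CEN-CEN clustering amplitude
    sigma_cen: float = 10_000.0   # clustering width (bp)
    peri_amp: float = 3.0         # intra peri-centromeric amplitude
    peri_sigma: float = 20_000.0
    loops: tuple[PlantedLoop, ...] = ()
    effects: ConditionEffects = field(default_factory=ConditionEffects)
    depth: float = 5e6            # expected total pair count per condition
    seed: int = 0

    def __post_init__(self):
        for name in ("c_intra", "c_inter", "peri_amp", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        lengths = self.genome.lengths
        for lp in self.loops:
            if lp.chrom not in lengths:
                raise ValueError(f"loop on unknown chromosome {lp.chrom!r}")
            if not (0 <= lp.anchor1 < lp.anchor2 < lengths[lp.chrom]):
                raise ValueError(f"loop anchors outside {lp.chrom}")

    def bin_table(self) -> BinTable:
        return BinTable(self.genome, self.binsize)


@dataclass
class SyntheticTruth:
    """Ground-truth record for recovery tests."""

    config: SyntheticConfig
    seed: Optional[int]
    expected_totals: dict[str, float]   # unscaled expected mass per condition
    scales: dict[str, float]            # depth / expected_total
    kappa_by_condition: dict[str, float]
    loops: tuple[PlantedLoop, ...]
    realized_totals: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rate model


def _bin_centers(config: SyntheticConfig, chrom: str) -> np.ndarray:
    length = config.genome.length(chrom)
    n = -(-length // config.binsize)
    centers = np.arange(n) * config.binsize + config.binsize / 2.0
    return np.minimum(centers, length - 0.5)


def _kappa(config: SyntheticConfig, condition: str) -> float:
    if condition == "control":
        return config.kappa
    return config.kappa * config.effects.kappa_fold


def _gauss(d: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def intra_rate_block(config: SyntheticConfig, chrom: str,
                     condition: str = "control") -> np.ndarray:
    """Dense symmetric expected-rate block for one chromosome (unscaled)."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    pos = _bin_centers(config, chrom)
    n = pos.size
    idx = np.arange(n)
    s = np.abs(np.subtract.outer(idx, idx)) * float(config.binsize)
    lam = config.c_intra * (s + config.s0) ** (-config.alpha)
    if chrom in config.genome.centromeres and config.peri_amp != 1.0:
        g = _gauss(pos - config.genome.centromere(chrom), config.peri_sigma)
        lam *= 1.0 + (config.peri_amp - 1.0) * np.outer(g, g)
    for lp in config.loops:
        if lp.chrom != chrom:
            continue
        g1 = _gauss(pos - lp.anchor1, lp.sigma)
        g2 = _gauss(pos - lp.anchor2, lp.sigma)
        lam *= 1.0 + (lp.strength - 1.0) * (np.outer(g1, g2) + np.outer(g2, g1))
    if condition == "depleted":
        for s_lo, s_hi, fold in config.effects.decay_band_folds:
            lam[(s >= s_lo) & (s < s_hi)] *= fold
        upper = np.triu(np.ones((n, n), dtype=bool), k=1)
        for lp in config.loops:
            if lp.chrom != chrom or lp.fold == 1.0:
                continue
            a1 = np.abs(pos - lp.anchor1) <= lp.fold_halfwidth
            a2 = np.abs(pos - lp.anchor2) <= lp.fold_halfwidth
            box = np.outer(a1, a2) & upper
            box = box | box.T
            lam[box] *= lp.fold
    return lam


def _cen_gauss(config: SyntheticConfig, chrom: str) -> np.ndarray:
    pos = _bin_centers(config, chrom)
    if chrom not in config.genome.centromeres:
        return np.zeros_like(pos)
    return _gauss(pos - config.genome.centromere(chrom), config.sigma_cen)


def inter_rate_block(config: SyntheticConfig, chrom1: str, chrom2: str,
                     condition: str = "control") -> np.ndarray:
    """Dense expected-rate block between two chromosomes (unscaled)."""
    kap = _kappa(config, condition)
    g1 = _cen_gauss(config, chrom1)
    g2 = _cen_gauss(config, chrom2)
    return config.c_inter * (1.0 + (kap - 1.0) * np.outer(g1, g2))


def _inter_block_sum(config: SyntheticConfig, chrom1: str, chrom2: str,
                     condition: str) -> float:
    kap = _kappa(config, condition)
    g1, g2 = _cen_gauss(config, chrom1), _cen_gauss(config, chrom2)
    return config.c_inter * (g1.size * g2.size + (kap - 1.0) * g1.sum() * g2.sum())


def expected_rate(config: SyntheticConfig, bins_i, bins_j,
                  condition: str = "control") -> np.ndarray:
    """Unscaled expected rate for (global bin i, global bin j) pairs."""
    bt = config.bin_table()
    bi = np.atleast_1d(np.asarray(bins_i, dtype=np.int64))
    bj = np.atleast_1d(np.asarray(bins_j, dtype=np.int64))
    bi, bj = np.broadcast_arrays(bi, bj)
    out = np.empty(bi.shape, dtype=float)
    blocks: dict[tuple[str, str], np.ndarray] = {}
    for k in range(bi.size):
        i, j = int(bi.flat[k]), int(bj.flat[k])
        ci, cj = bt.chrom_of(i), bt.chrom_of(j)
        li, lj = i - bt.chrom_offset(ci), j - bt.chrom_offset(cj)
        if ci == cj:
            key = (ci, ci)
            if key not in blocks:
                blocks[key] = intra_rate_block(config, ci, condition)
            out.flat[k] = blocks[key][li, lj]
        else:
            key = (ci, cj)
            if key not in blocks:
                blocks[key] = inter_rate_block(config, ci, cj, condition)
            out.flat[k] = blocks[key][li, lj]
    return out if out.size > 1 else float(out.flat[0])


def expected_matrix(config: SyntheticConfig, condition: str = "control",
                    scope: str = "intra", chroms: Optional[Sequence[str]] = None,
                    flank: int = 60_000) -> ContactMatrix:
    """Noiseless expected-rate matrix (unscaled) as a ContactMatrix.

    ``scope='intra'`` fills intra-chromosomal blocks (optionally for a subset
    of chromosomes), ``'inter-cen'`` only the inter-chromosomal windows of
    +/-``flank`` around centromere pairs (enough for pile-up analysis), and
    ``'full'`` everything (small genomes only).
    """
    bt = config.bin_table()
    names = list(chroms) if chroms is not None else bt.chrom_names
    rows, cols, vals = [], [], []
    if scope in ("intra", "full"):
        for chrom in names:
            lo, _ = bt.chrom_range(chrom)
            lam = intra_rate_block(config, chrom, condition)
            iu, ju = np.triu_indices(lam.shape[0])
            rows.append(iu + lo)
            cols.append(ju + lo)
            vals.append(lam[iu, ju])
    if scope in ("inter-cen", "full"):
        half = flank // config.binsize
        for a, c1 in enumerate(names):
            for c2 in names[a + 1:]:
                lam = inter_rate_block(config, c1, c2, condition)
                lo1, hi1 = bt.chrom_range(c1)
                lo2, hi2 = bt.chrom_range(c2)
                if scope == "full":
                    r = np.repeat(np.arange(lam.shape[0]), lam.shape[1])
                    c = np.tile(np.arange(lam.shape[1]), lam.shape[0])
                else:
                    if c1 not in config.genome.centromeres or \
                       c2 not in config.genome.centromeres:
                        continue
                    cen1 = bt.locate(c1, config.genome.centromere(c1)) - lo1
                    cen2 = bt.locate(c2, config.genome.centromere(c2)) - lo2
                    w1 = np.arange(max(cen1 - half, 0),
                                   min(cen1 + half + 1, hi1 - lo1))
                    w2 = np.arange(max(cen2 - half, 0),
                                   min(cen2 + half + 1, hi2 - lo2))
                    r = np.repeat(w1, w2.size)
                    c = np.tile(w2, w1.size)
                rows.append(r + lo1)
                cols.append(c + lo2)
                vals.append(lam[r, c])
    return ContactMatrix(
        bt, np.concatenate(rows), np.concatenate(cols), np.concatenate(vals),
        kind="balanced", meta={"synthetic_expected": True, "condition": condition},
    )


# ---------------------------------------------------------------------------
# sampling


def _expected_total(config: SyntheticConfig, condition: str) -> float:
    total = 0.0
    for chrom in config.genome.names:
        lam = intra_rate_block(config, chrom, condition)
        total += np.triu(lam).sum()
    names = config.genome.names
    for a, c1 in enumerate(names):
        for c2 in names[a + 1:]:
            total += _inter_block_sum(config, c1, c2, condition)
    return float(total)


def simulate_pair(config: SyntheticConfig, seed: Optional[int] = None
                  ) -> tuple[ContactMatrix, ContactMatrix, SyntheticTruth]:
    """Draw a (control, depleted) matrix pair with Poisson count noise.

    Counts are independent Poisson draws per upper-triangle cell, with rates
    scaled so each condition's expected total equals ``config.depth``.  Fully
    reproducible from ``seed`` (defaults to ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(CONDITIONS))
    bt = config.bin_table()
    names = config.genome.names

    matrices = {}
    totals, scales, realized = {}, {}, {}
    for cond, child in zip(CONDITIONS, children):
        rng = np.random.default_rng(child)
        totals[cond] = _expected_total(config, cond)
        scale = config.depth / totals[cond]
        scales[cond] = scale
        rows, cols, vals = [], [], []
        for chrom in names:
            lo, _ = bt.chrom_range(chrom)
            lam = intra_rate_block(config, chrom, cond)
            iu, ju = np.triu_indices(lam.shape[0])
            counts = rng.poisson(scale * lam[iu, ju])
            nz = counts > 0
            rows.append(iu[nz] + lo)
            cols.append(ju[nz] + lo)
            vals.append(counts[nz])
        for a, c1 in enumerate(names):
            lo1, _ = bt.chrom_range(c1)
            for c2 in names[a + 1:]:
                lo2, _ = bt.chrom_range(c2)
                lam = inter_rate_block(config, c1, c2, cond)
                counts = rng.poisson(scale * lam)
                r, c = np.nonzero(counts)
                rows.append(r + lo1)
                cols.append(c + lo2)
                vals.append(counts[r, c])
        m = ContactMatrix(
            bt,
            np.concatenate(rows), np.concatenate(cols),
            np.concatenate(vals).astype(float),
            kind="raw",
            meta={"synthetic": True, "condition": cond, "seed": seed,
                  "depth": config.depth},
        )
        realized[cond] = int(m.total)
        matrices[cond] = m

    truth = SyntheticTruth(
        config=config, seed=seed, expected_totals=totals, scales=scales,
        kappa_by_condition={c: _kappa(config, c) for c in CONDITIONS},
        loops=config.loops, realized_totals=realized,
    )
    return matrices["control"], matrices["depleted"], truth


# ---------------------------------------------------------------------------
# closure helpers


def recover_alpha(profile: DistanceDecayProfile,
                  fit_range: tuple[int, int] = (2_000, 50_000),
                  s0: float = 0.0) -> float:
    """Decay exponent from a distance-decay profile: negated least-squares
    slope of log CP against log(s + s0) over the fit range."""
    lo, hi = fit_range
    sel = (profile.distances >= lo) & (profile.distances <= hi) & (profile.values > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 usable strata in the fit range")
    x = np.log(profile.distances[sel] + s0)
    y = np.log(profile.values[sel])
    slope = np.polyfit(x, y, 1)[0]
    return float(-slope)


def car_like_loops(genome: GenomeModel, n: int = 20,
                   distances: Sequence[int] = (8_000, 10_000, 12_000),
                   strength: float = 3.0, sigma: float = 2_000.0,
                   fold: float = 1.0, fold_halfwidth: float = 8_000.0,
                   cen_margin: int = 40_000, end_margin: int = 20_000
                   ) -> tuple[PlantedLoop, ...]:
    """Deterministic placement of CAR-like loop anchors on chromosome arms.

    Slots are taken first on right arms (anchor1 at centromere + cen_margin),
    then on left arms (anchor1 at centromere - 2*cen_margin), cycling through
    chromosomes in genome order; loop distances cycle through ``distances``.
    """
    slots = []
    for arm in ("right", "left"):
        for chrom, length in genome.chromosomes:
            if chrom not in genome.centromeres:
                continue
            cen = genome.centromere(chrom)
            a1 = cen + cen_margin if arm == "right" else cen - 2 * cen_margin
            slots.append((chrom, a1, length))
    loops = []
    k = 0
    for chrom, a1, length in slots:
        if len(loops) >= n:
            break
        d = int(distances[k % len(distances)])
        a2 = a1 + d
        if a1 < end_margin or a2 > length - end_margin:
            continue
        loops.append(PlantedLoop(chrom, int(a1), int(a2), strength=strength,
                                 sigma=sigma, fold=fold,
                                 fold_halfwidth=fold_halfwidth))
        k += 1
    if len(loops) < n:
        raise ValueError(f"could only place {len(loops)} of {n} loops")
    return tuple(loops)


def default_config(genome: Optional[GenomeModel] = None,
                   loops: tuple[PlantedLoop, ...] = (),
                   effects: Optional[ConditionEffects] = None,
                   depth: float = 5e6, seed: int = 0, **overrides
                   ) -> SyntheticConfig:
    """Full 16-chromosome sacCer3 configuration at Hi-C-realistic settings."""
    return SyntheticConfig(
        genome=genome or saccer3_genome(),
        loops=loops,
        effects=effects or ConditionEffects(),
        depth=depth,
        seed=seed,
        **overrides,
    )


def demo_config(loops: tuple[PlantedLoop, ...] = (),
                effects: Optional[ConditionEffects] = None,
                depth: float = 5e5, seed: int = 0, **overrides) -> SyntheticConfig:
    """Small 4-chromosome configuration for fast tests."""
    return SyntheticConfig(
        genome=demo_genome(),
        loops=loops,
        effects=effects or ConditionEffects(),
        depth=depth,
        seed=seed,
        **overrides,
    )
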