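"""Inter-centromere (CEN-CEN) aggregate pile-up analysis.

For every unordered pair of chromosomes the inter-chromosomal sub-matrix
centered on the two centromere bins is extracted with a +/-F flank (the
chromosome earlier in genome order on rows), and blocks are averaged
cell-wise over valid cells.  Cells extending past a chromosome end (or
falling on ICE-masked bins) are missing for that pair and do not enter the
average.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .genome import BinTable, GenomeModel
from .matrix import ContactMatrix
from .stats import RankSumResult, wilcoxon_rank_sum_one_sided

__all__ = [
    "PileupResult",
    "CentralWindowStats",
    "centromere_bin",
    "cen_cen_pileup",
    "pileup_log2_ratio",
    "central_window",
    "compare_central_windows",
]


def centromere_bin(genome: GenomeModel, bin_table: BinTable, chrom: str) -> int:
    """Global index of the bin containing the point-centromere midpoint."""
    return bin_table.locate(chrom, genome.centromere(chrom))


@dataclass
class PileupResult:
    """Averaged inter CEN-CEN window.

    ``window`` is a square (2F/binsize + 1)-sided grid of mean contact values
    (NaN where no pair contributed); ``valid_count`` holds the number of
    chromosome pairs contributing to each cell.
    """

    window: np.ndarray
    valid_count: np.ndarray
    flank: int
    binsize: int
    n_pairs_averaged: int

    def __post_init__(self):
        side = self.window.shape[0]
        if self.window.shape != (side, side) or side % 2 != 1:
            raise ValueError("pile-up window must be square with odd side")
        if np.any(self.valid_count > self.n_pairs_averaged):
            raise ValueError("valid_count cannot exceed the number of pairs")

    @property
    def side(self) -> int:
        return self.window.shape[0]


def cen_cen_pileup(matrix: ContactMatrix, genome: Optional[GenomeModel] = None,
                   flank: int = 50_000) -> PileupResult:
    """Average the inter-chromosomal CEN-CEN blocks over all chromosome pairs."""
    genome = genome or matrix.bins.genome
    bt = matrix.bins
    cen_chroms = [c for c in bt.chrom_names if c in genome.centromeres]
    if len(cen_chroms) < 2:
        raise ValueError("need centromeres on at least 2 chromosomes")
    half = flank // bt.binsize
    side = 2 * half + 1
    csr = matrix.to_csr_sym()

    sums = np.zeros((side, side))
    counts = np.zeros((side, side), dtype=np.int64)
    n_pairs = 0
    for c1, c2 in combinations(cen_chroms, 2):
        n_pairs += 1
        block = np.full((side, side), np.nan)
        idx = {}
        for c in (c1, c2):
            lo, hi = bt.chrom_range(c)
            cen = centromere_bin(genome, bt, c)
            offs = np.arange(-half, half + 1)
            gi = cen + offs
            ok = (gi >= lo) & (gi < hi)
            if matrix.mask is not None:
                ok &= ~matrix.mask[np.clip(gi, lo, hi - 1)]
            idx[c] = (gi, ok)
        gi1, ok1 = idx[c1]
        gi2, ok2 = idx[c2]
        sub = np.asarray(
            csr[np.clip(gi1, 0, bt.nbins - 1), :][:, np.clip(gi2, 0, bt.nbins - 1)]
            .todense(), dtype=float)
        valid = np.outer(ok1, ok2)
        block[valid] = sub[valid]
        # One oriented block per unordered pair (first chromosome in genome
        # order on rows).  Averaging a block with its transpose would leave
        # the window mean unchanged but duplicate cell values across the
        # window, which breaks the independence the central-window rank-sum
        # test relies on.
        use = ~np.isnan(block)
        sums[use] += block[use]
        counts[use] += 1

    window = np.full((side, side), np.nan)
    nz = counts > 0
    window[nz] = sums[nz] / counts[nz]
    return PileupResult(window, counts, flank, bt.binsize, n_pairs)


def pileup_log2_ratio(p_iaa: PileupResult, p_con: PileupResult) -> np.ndarray:
    """Cell-wise log2(iaa / con); cells missing in either pile-up are NaN."""
    if p_iaa.flank != p_con.flank or p_iaa.binsize != p_con.binsize:
        raise ValueError("pile-ups must share flank and bin size")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(p_iaa.window / p_con.window)
    r[~np.isfinite(r)] = np.nan
    return r


@dataclass
class CentralWindowStats:
    """Values of the side x side cells at the pile-up center."""

    values: np.ndarray
    side: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))


def central_window(pileup: PileupResult, side: int = 5) -> CentralWindowStats:
    """Extract the central side x side cells of the pile-up (side odd)."""
    if side % 2 != 1:
        raise ValueError("central window side must be odd")
    if side > pileup.side:
        raise ValueError("central window larger than the pile-up window")
    c = pileup.side // 2
    h = side // 2
    vals = pileup.window[c - h:c + h + 1, c - h:c + h + 1].ravel()
    return CentralWindowStats(vals, side)


def compare_central_windows(s_con: CentralWindowStats, s_iaa: CentralWindowStats,
                            direction: str = "depletion"
                            ) -> tuple[float, RankSumResult]:
    """Fold change and one-sided rank-sum p-value between central windows.

    ``direction='depletion'`` reports fold = mean(con)/mean(iaa) and tests
    whether the +IAA values are stochastically smaller than control;
    ``'gain'`` reports the reciprocal orientation.
    """
    if s_con.side != s_iaa.side:
        raise ValueError("central windows must have equal side")
    con = s_con.values[~np.isnan(s_con.values)]
    iaa = s_iaa.values[~np.isnan(s_iaa.values)]
    if direction == "depletion":
        denom = np.mean(iaa)
        if denom == 0:
            raise ZeroDivisionError("zero mean in the +IAA central window")
        fold = float(np.mean(con) / denom)
        test = wilcoxon_rank_sum_one_sided(iaa, con, alternative="less")
    elif direction == "gain":
        denom = np.mean(con)
        if denom == 0:
            raise ZeroDivisionError("zero mean in the control central window")
        fold = float(np.mean(iaa) / denom)
        test = wilcoxon_rank_sum_one_sided(iaa, con, alternative="greater")
    else:
        raise ValueError("direction must be 'depletion' or 'gain'")
    return fold, test
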