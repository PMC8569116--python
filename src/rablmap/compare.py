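"""Differential contact-map statistics.

Log2 ratio maps between conditions, distance-decay (contact probability)
curves and their log-ratios, short-versus-long (SVL) interaction ratios, and
virtual-4C centromere profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .genome import GenomeModel
from .matrix import ContactMatrix

__all__ = [
    "DistanceDecayProfile",
    "SVLResult",
    "log2_ratio_map",
    "contact_probability",
    "cp_log2_ratio",
    "svl_ratio",
    "virtual_4c",
    "default_strata_edges",
]


# ---------------------------------------------------------------------------
# log2 ratio maps


def log2_ratio_map(A: ContactMatrix, B: ContactMatrix,
                   eps: Optional[float] = None,
                   chroms: Optional[list[str]] = None) -> dict[str, np.ndarray]:
    """Per-chromosome dense log2((A+eps)/(B+eps)) maps; A is the perturbed
    condition, B the control.

    Cells where both matrices are zero are reported as NaN (missing), not 0.
    The default pseudocount is the smallest positive value found in either
    matrix, which keeps single-condition zeros finite without swamping signal.
    """
    if not A.bins.same_binning(B.bins):
        raise ValueError("matrices must share a bin table")
    if eps is None:
        pos = np.concatenate([A.val[A.val > 0], B.val[B.val > 0]])
        if pos.size == 0:
            raise ValueError("both matrices are empty; no default pseudocount")
        eps = float(pos.min())
    if eps < 0:
        raise ValueError("pseudocount must be nonnegative")
    csr_a, csr_b = A.to_csr_sym(), B.to_csr_sym()
    out: dict[str, np.ndarray] = {}
    for chrom in chroms or A.bins.chrom_names:
        a = A.chrom_block(chrom, csr_a)
        b = B.chrom_block(chrom, csr_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2((a + eps) / (b + eps))
        r[(a == 0) & (b == 0)] = np.nan
        out[chrom] = r
    return out


# ---------------------------------------------------------------------------
# distance decay


@dataclass
class DistanceDecayProfile:
    """Mean contact value per genomic-distance stratum.

    ``distances`` are stratum start distances in bp (positive multiples of the
    bin size, strictly increasing); ``values`` the stratum means (contacts per
    bin pair, or probabilities when ``mode='probability'``); ``n_pairs`` the
    number of bin pairs in each stratum.
    """

    binsize: int
    distances: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    mode: str = "mean"  # "mean" | "probability"

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("stratum distances must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance": self.distances,
            "value": self.values,
            "n_pairs": self.n_pairs,
        })


def default_strata_edges(max_lag: int, binsize: int, linear_to: int = 50_000,
                         log_step: float = 1.12) -> np.ndarray:
    """Stratum edges in bin lags: 1-bin granularity out to ``linear_to`` bp,
    then geometric steps of ``log_step`` per stratum."""
    lin_max = min(max_lag, max(1, linear_to // binsize))
    edges = list(range(1, lin_max + 1))
    nxt = float(lin_max)
    while edges[-1] <= max_lag:
        nxt *= log_step
        step = max(int(np.floor(nxt)), edges[-1] + 1)
        edges.append(step)
    edges = [e for e in edges if e <= max_lag + 1]
    if edges[-1] != max_lag + 1:
        edges.append(max_lag + 1)
    return np.asarray(edges, dtype=np.int64)


def _per_lag_sums(matrix: ContactMatrix, chroms: list[str]):
    """Total contact value and valid pair count for every intra-chromosomal lag."""
    bt = matrix.bins
    max_lag = max(bt.chrom_nbins(c) for c in chroms) - 1
    if max_lag < 1:
        raise ValueError("chromosome shorter than 2 bins")
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)

    ranges = {c: bt.chrom_range(c) for c in chroms}
    # entry sums
    for c in chroms:
        lo, hi = ranges[c]
        sel = (matrix.row >= lo) & (matrix.row < hi) & (matrix.col < hi)
        lags = matrix.col[sel] - matrix.row[sel]
        np.add.at(sums, lags, matrix.val[sel])
    # pair counts (mask-aware: pairs with a masked bin are not counted)
    for c in chroms:
        lo, hi = ranges[c]
        n = hi - lo
        u = np.ones(n) if matrix.mask is None else (~matrix.mask[lo:hi]).astype(float)
        ac = fftconvolve(u, u[::-1])  # autocorrelation; lag k at index n-1+k
        k = np.arange(0, min(n, max_lag + 1))
        counts[k] += np.round(ac[n - 1 + k])
    return sums, counts.astype(np.int64), max_lag


def contact_probability(matrix: ContactMatrix, chrom: Optional[str] = None,
                        mode: str = "mean",
                        strata_edges: Optional[np.ndarray] = None,
                        linear_to: int = 50_000,
                        log_step: float = 1.12) -> DistanceDecayProfile:
    """Distance-decay profile: mean contact value per genomic-distance stratum.

    Absent entries count as 0 in the mean; when the matrix carries an ICE
    mask, pairs involving masked bins are excluded from both numerator and
    denominator.  ``chrom=None`` pools all intra-chromosomal pairs genome-wide.
    """
    if mode not in ("mean", "probability"):
        raise ValueError("mode must be 'mean' or 'probability'")
    chroms = [chrom] if chrom is not None else matrix.bins.chrom_names
    sums, counts, max_lag = _per_lag_sums(matrix, chroms)
    binsize = matrix.bins.binsize
    if strata_edges is None:
        strata_edges = default_strata_edges(max_lag, binsize, linear_to, log_step)
    edges = np.asarray(strata_edges, dtype=np.int64)

    dist, vals, npairs = [], [], []
    lag_index = np.arange(max_lag + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (lag_index >= lo) & (lag_index < hi)
        n = int(counts[sel].sum())
        if n == 0:
            continue
        dist.append(int(lo) * binsize)
        vals.append(sums[sel].sum() / n)
        npairs.append(n)
    vals = np.asarray(vals)
    if mode == "probability":
        total = vals.sum()
        if total > 0:
            vals = vals / total
    return DistanceDecayProfile(binsize, np.asarray(dist), vals,
                                np.asarray(npairs), mode)


def cp_log2_ratio(p_iaa: DistanceDecayProfile,
                  p_con: DistanceDecayProfile) -> pd.DataFrame:
    """Pointwise log2(CP_iaa / CP_con) along distance.

    Strata where either profile is zero are dropped; the number dropped is
    recorded in ``DataFrame.attrs['n_dropped']``.
    """
    if p_iaa.binsize != p_con.binsize or not np.array_equal(
            p_iaa.distances, p_con.distances):
        raise ValueError("profiles must share identical strata")
    ok = (p_iaa.values > 0) & (p_con.values > 0)
    df = pd.DataFrame({
        "distance": p_iaa.distances[ok],
        "log2_ratio": np.log2(p_iaa.values[ok] / p_con.values[ok]),
    })
    df.attrs["n_dropped"] = int((~ok).sum())
    return df


# ---------------------------------------------------------------------------
# SVL


@dataclass
class SVLResult:
    """Per-chromosome short/long sums and their ratio at threshold L (bp).

    Distances strictly below L are short, distances >= L (including exactly L)
    are long.  Chromosomes shorter than L get a NaN ratio; all short-range
    mass with empty long range yields +inf.
    """

    threshold: int
    table: pd.DataFrame  # columns: chrom, short_sum, long_sum, ratio

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()


def svl_ratio(matrix: ContactMatrix, L: int = 100_000) -> SVLResult:
    bt = matrix.bins
    if L % bt.binsize != 0:
        raise ValueError("L must be a multiple of the bin size")
    cut = L // bt.binsize
    rows = []
    for chrom, length in bt.genome.chromosomes:
        lo, hi = bt.chrom_range(chrom)
        sel = (matrix.row >= lo) & (matrix.row < hi) & (matrix.col < hi)
        lags = matrix.col[sel] - matrix.row[sel]
        vals = matrix.val[sel]
        short = float(vals[(lags > 0) & (lags < cut)].sum())
        long_ = float(vals[lags >= cut].sum())
        if length < L:
            warnings.warn(f"{chrom} is shorter than L={L}; SVL ratio undefined")
            ratio = np.nan
        elif long_ > 0:
            ratio = short / long_
        elif short > 0:
            ratio = np.inf
        else:
            ratio = np.nan
        rows.append((chrom, short, long_, ratio))
    return SVLResult(L, pd.DataFrame(rows, columns=["chrom", "short_sum",
                                                    "long_sum", "ratio"]))


# ---------------------------------------------------------------------------
# virtual 4C


def virtual_4c(matrix: ContactMatrix, chrom: str,
               genome: Optional[GenomeModel] = None) -> pd.DataFrame:
    """Contact profile of the centromere bin against every bin of its chromosome.

    Returns a table of (start, value); masked bins are NaN.  Because storage
    is symmetric, the profile is identical whether read as row or column.
    """
    genome = genome or matrix.bins.genome
    mid = genome.centromere(chrom)
    bt = matrix.bins
    cen = bt.locate(chrom, mid)
    lo, hi = bt.chrom_range(chrom)
    row = np.asarray(matrix.to_csr_sym()[cen, lo:hi].todense()).ravel()
    if matrix.mask is not None:
        row = row.astype(float)
        row[matrix.mask[lo:hi]] = np.nan
        if matrix.mask[cen]:
            row[:] = np.nan
    starts = np.arange(hi - lo, dtype=np.int64) * bt.binsize
    return pd.DataFrame({"start": starts, "value": row})
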