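"""Replicate agreement: matrix Pearson correlation and the stratum-adjusted
correlation coefficient (SCC).

The SCC smooths both maps with a 2D mean filter, computes a Pearson
correlation within every genomic-distance stratum up to a maximum distance,
and combines the per-stratum correlations with weights N_s * sd1_s * sd2_s.
Strata are pooled genome-wide, which keeps the statistic well defined for
small chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .matrix import ContactMatrix

__all__ = ["SCCResult", "mean_filter", "scc", "pearson_matrices"]


def _smooth_block(x: np.ndarray, h: int) -> np.ndarray:
    """Mean over the (2h+1)^2 neighborhood clipped to the block: absent cells
    count as 0 and the divisor is the number of in-range cells."""
    if h == 0:
        return x
    size = 2 * h + 1
    s = uniform_filter(x, size=size, mode="constant", cval=0.0) * size * size
    n = uniform_filter(np.ones_like(x), size=size, mode="constant", cval=0.0) * size * size
    return s / np.round(n)


def mean_filter(matrix: ContactMatrix, h: int) -> ContactMatrix:
    """2D mean filter of every intra-chromosomal block (inter entries pass
    through unchanged); ``h`` is the half-width in bins."""
    if h < 0:
        raise ValueError("h must be >= 0")
    if h == 0:
        return matrix.copy()
    bt = matrix.bins
    csr = matrix.to_csr_sym()
    rows, cols, vals = [], [], []
    for chrom in bt.chrom_names:
        lo, _ = bt.chrom_range(chrom)
        block = _smooth_block(matrix.chrom_block(chrom, csr), h)
        iu, ju = np.triu_indices(block.shape[0])
        v = block[iu, ju]
        keep = v != 0
        rows.append(iu[keep] + lo)
        cols.append(ju[keep] + lo)
        vals.append(v[keep])
    inter = ~matrix.intra_mask()
    rows.append(matrix.row[inter])
    cols.append(matrix.col[inter])
    vals.append(matrix.val[inter])
    return ContactMatrix(
        bt, np.concatenate(rows), np.concatenate(cols), np.concatenate(vals),
        kind=matrix.kind, mask=None if matrix.mask is None else matrix.mask.copy(),
        meta={**matrix.meta, "mean_filter_h": h},
    )


@dataclass
class SCCResult:
    """Stratum-adjusted correlation coefficient with its per-stratum table.

    ``strata`` columns: distance (bp), r (Pearson within stratum), n_pairs,
    sd1, sd2.  ``scc = sum(w_s r_s) / sum(w_s)`` with
    ``w_s = n_pairs * sd1 * sd2`` over strata with positive weight.
    """

    scc: float
    strata: pd.DataFrame
    h: int
    max_dist: int

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.scc <= 1.0 + 1e-12):
            raise ValueError("scc outside [-1, 1]")


def scc(A: ContactMatrix, B: ContactMatrix, h: int = 5,
        max_dist: int = 100_000) -> SCCResult:
    """Stratum-adjusted correlation between two contact maps.

    Both maps are smoothed with ``mean_filter(h)``; intra-chromosomal cell
    pairs with 0 < distance <= max_dist are stratified by distance (pooled
    over chromosomes), and per-stratum Pearson correlations are combined with
    variance- and size-dependent weights.
    """
    if not A.bins.same_binning(B.bins):
        raise ValueError("matrices must share a bin table")
    bt = A.bins
    K = max_dist // bt.binsize
    if K < 1:
        raise ValueError("max_dist smaller than one bin")
    csr_a, csr_b = A.to_csr_sym(), B.to_csr_sym()
    per_k_a: list[list[np.ndarray]] = [[] for _ in range(K + 1)]
    per_k_b: list[list[np.ndarray]] = [[] for _ in range(K + 1)]
    for chrom in bt.chrom_names:
        lo, hi = bt.chrom_range(chrom)
        n = hi - lo
        if n < 2:
            continue
        a = _smooth_block(A.chrom_block(chrom, csr_a), h)
        b = _smooth_block(B.chrom_block(chrom, csr_b), h)
        bad = np.zeros(n, dtype=bool)
        if A.mask is not None:
            bad |= A.mask[lo:hi]
        if B.mask is not None:
            bad |= B.mask[lo:hi]
        for k in range(1, min(K, n - 1) + 1):
            da = np.diagonal(a, offset=k)
            db = np.diagonal(b, offset=k)
            ok = ~(bad[:-k] | bad[k:])
            if ok.any():
                per_k_a[k].append(da[ok])
                per_k_b[k].append(db[ok])

    rows = []
    num = den = 0.0
    for k in range(1, K + 1):
        if not per_k_a[k]:
            continue
        xa = np.concatenate(per_k_a[k])
        xb = np.concatenate(per_k_b[k])
        n_s = xa.size
        sd1 = float(np.std(xa))
        sd2 = float(np.std(xb))
        if n_s < 2 or sd1 == 0.0 or sd2 == 0.0:
            r = np.nan
            w = 0.0
        else:
            r = float(np.corrcoef(xa, xb)[0, 1])
            w = n_s * sd1 * sd2
            num += w * r
            den += w
        rows.append((k * bt.binsize, r, n_s, sd1, sd2))
    if den == 0.0:
        raise ValueError("no usable strata (all constant or empty)")
    table = pd.DataFrame(rows, columns=["distance", "r", "n_pairs", "sd1", "sd2"])
    return SCCResult(float(np.clip(num / den, -1.0, 1.0)), table, h, max_dist)


def pearson_matrices(A: ContactMatrix, B: ContactMatrix) -> float:
    """Pearson correlation over the union of nonzero cells (absent = 0),
    intra- plus inter-chromosomal."""
    if not A.bins.same_binning(B.bins):
        raise ValueError("matrices must share a bin table")
    ca = A.to_coo_upper().tocsr()
    cb = B.to_coo_upper().tocsr()
    union = ((ca != 0) + (cb != 0)).tocoo()
    if union.nnz == 0:
        raise ValueError("both matrices are empty")
    a = np.asarray(ca[union.row, union.col]).ravel()
    b = np.asarray(cb[union.row, union.col]).ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance over the union of nonzero cells")
    return float(np.corrcoef(a, b)[0, 1])
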