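"""Sparse symmetric contact matrices on a genome-wide bin index space.

Entries are stored as an upper-triangle triplet set (i <= j); the matrix is
symmetric by contract.  Values are raw pair counts or balanced (bias-corrected)
contact values, distinguished by ``kind``.  Bins excluded during balancing are
recorded in ``mask`` so downstream statistics can treat them as missing rather
than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .genome import BinTable

__all__ = ["ContactMatrix"]


@dataclass
class ContactMatrix:
    bins: BinTable
    row: np.ndarray
    col: np.ndarray
    val: np.ndarray
    kind: str = "raw"  # "raw" | "balanced"
    mask: Optional[np.ndarray] = None  # bool per bin, True = excluded bin
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.row = np.asarray(self.row, dtype=np.int64)
        self.col = np.asarray(self.col, dtype=np.int64)
        self.val = np.asarray(self.val, dtype=np.float64)
        if not (self.row.shape == self.col.shape == self.val.shape):
            raise ValueError("row/col/val must have identical shapes")
        if self.kind not in ("raw", "balanced"):
            raise ValueError(f"kind must be 'raw' or 'balanced', got {self.kind!r}")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_entries(cls, bins, row, col, val, kind="raw", mask=None, meta=None,
                     check=True):
        """Build from triplets, swapping so i <= j; duplicates are an error."""
        row = np.asarray(row, dtype=np.int64)
        col = np.asarray(col, dtype=np.int64)
        val = np.asarray(val, dtype=np.float64)
        swap = row > col
        r = np.where(swap, col, row)
        c = np.where(swap, row, col)
        m = cls(bins, r, c, val, kind=kind, mask=mask, meta=meta or {})
        if check:
            m.validate()
        return m

    @classmethod
    def from_dense(cls, bins, dense, kind="raw", tol=0.0):
        """Upper triangle (incl. diagonal) of a dense symmetric array."""
        dense = np.asarray(dense, dtype=np.float64)
        n = bins.nbins
        if dense.shape != (n, n):
            raise ValueError(f"dense shape {dense.shape} != ({n}, {n})")
        iu, ju = np.triu_indices(n)
        v = dense[iu, ju]
        keep = np.abs(v) > tol
        return cls(bins, iu[keep], ju[keep], v[keep], kind=kind)

    def validate(self):
        n = self.bins.nbins
        if self.row.size:
            if self.row.min() < 0 or self.col.max() >= n:
                raise ValueError("bin index out of range")
            if np.any(self.row > self.col):
                raise ValueError("entries must satisfy i <= j (upper triangle)")
            if np.any(self.val < 0):
                raise ValueError("contact values must be nonnegative")
            key = self.row * n + self.col
            if np.unique(key).size != key.size:
                raise ValueError("duplicate (i, j) entries")
        return self

    # -- basic properties -------------------------------------------------

    @property
    def nbins(self) -> int:
        return self.bins.nbins

    @property
    def nnz(self) -> int:
        return int(self.row.size)

    @property
    def total(self) -> float:
        """Sum of stored (upper-triangle) values; each unordered pair once."""
        return float(self.val.sum())

    def is_integer(self) -> bool:
        return bool(np.all(self.val == np.round(self.val)))

    def copy(self) -> "ContactMatrix":
        return replace(
            self,
            row=self.row.copy(),
            col=self.col.copy(),
            val=self.val.copy(),
            mask=None if self.mask is None else self.mask.copy(),
            meta=dict(self.meta),
        )

    def scaled(self, c: float) -> "ContactMatrix":
        if c <= 0:
            raise ValueError("scale factor must be positive")
        out = self.copy()
        out.val = out.val * c
        return out

    # -- views ------------------------------------------------------------

    def to_coo_upper(self) -> sp.coo_matrix:
        n = self.nbins
        return sp.coo_matrix((self.val, (self.row, self.col)), shape=(n, n))

    def to_csr_sym(self) -> sp.csr_matrix:
        """Full symmetric CSR (diagonal counted once)."""
        upper = self.to_coo_upper().tocsr()
        lower = upper.T.tocsr()
        diag = sp.diags(upper.diagonal())
        return (upper + lower - diag).tocsr()

    def intra_mask(self) -> np.ndarray:
        """Boolean over entries: both bins on the same chromosome."""
        offsets = np.array(
            [self.bins.chrom_offset(c) for c in self.bins.chrom_names] + [self.nbins]
        )
        ci = np.searchsorted(offsets, self.row, side="right")
        cj = np.searchsorted(offsets, self.col, side="right")
        return ci == cj

    def chrom_block(self, chrom: str, sym_csr: Optional[sp.csr_matrix] = None) -> np.ndarray:
        """Dense symmetric intra-chromosomal block for one chromosome."""
        lo, hi = self.bins.chrom_range(chrom)
        csr = self.to_csr_sym() if sym_csr is None else sym_csr
        return np.asarray(csr[lo:hi, lo:hi].todense(), dtype=np.float64)

    def inter_block(self, chrom1: str, chrom2: str,
                    sym_csr: Optional[sp.csr_matrix] = None) -> np.ndarray:
        """Dense inter-chromosomal block (rows: chrom1 bins, cols: chrom2 bins)."""
        lo1, hi1 = self.bins.chrom_range(chrom1)
        lo2, hi2 = self.bins.chrom_range(chrom2)
        csr = self.to_csr_sym() if sym_csr is None else sym_csr
        return np.asarray(csr[lo1:hi1, lo2:hi2].todense(), dtype=np.float64)

    def chrom_mask(self, chrom: str) -> Optional[np.ndarray]:
        if self.mask is None:
            return None
        lo, hi = self.bins.chrom_range(chrom)
        return self.mask[lo:hi]

    # -- rebinning ---------------------------------------------------------

    def rebin(self, factor: int) -> "ContactMatrix":
        """Aggregate to ``factor``-times-coarser bins; totals are conserved."""
        if factor < 1:
            raise ValueError("rebin factor must be >= 1")
        if factor == 1:
            return self.copy()
        coarse = BinTable(self.bins.genome, self.bins.binsize * factor)
        # map old global index -> new global index (monotone within genome order)
        mapping = np.empty(self.nbins, dtype=np.int64)
        for name in self.bins.chrom_names:
            lo, hi = self.bins.chrom_range(name)
            off = coarse.chrom_offset(name)
            local = np.arange(hi - lo, dtype=np.int64) // factor
            mapping[lo:hi] = off + local
        r = mapping[self.row]
        c = mapping[self.col]
        n = coarse.nbins
        agg = sp.coo_matrix((self.val, (r, c)), shape=(n, n)).tocsr().tocoo()
        return ContactMatrix(
            coarse, agg.row, agg.col, agg.data, kind=self.kind, meta=dict(self.meta)
        )
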