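"""Sequencing-depth equalization and ICE matrix balancing.

Depth equalization draws an exact multivariate-hypergeometric subsample of
read pairs from the binned counts (sampling pairs without replacement at the
matrix level is the exact equivalent of subsampling valid pairs before
binning).  ICE iteratively rescales per-bin multiplicative biases until the
unmasked marginals are uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .matrix import ContactMatrix

__all__ = ["BiasVector", "min_depth", "downsample_counts", "ice_balance"]


@dataclass
class BiasVector:
    """Per-bin multiplicative biases b_i; masked (excluded) bins are NaN."""

    values: np.ndarray          # float, NaN on masked bins
    mask: np.ndarray            # bool, True = excluded

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have identical length")
        ok = self.values[~self.mask]
        if ok.size and not np.all(ok > 0):
            raise ValueError("unmasked bias values must be positive")


def min_depth(matrices: Sequence[ContactMatrix]) -> int:
    """Minimum total pair count across libraries (the downsampling target)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("min_depth needs at least one matrix")
    return int(min(round(m.total) for m in matrices))


def downsample_counts(matrix: ContactMatrix, target_total: int,
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None) -> ContactMatrix:
    """Draw exactly ``target_total`` pairs without replacement from the counts.

    The output is a multivariate-hypergeometric draw over the nonzero cells:
    totals are exact, 0 <= out_ij <= in_ij everywhere, and the draw is
    reproducible given ``seed``.
    """
    if not matrix.is_integer():
        raise ValueError("downsampling requires integer raw counts")
    counts = np.round(matrix.val).astype(np.int64)
    total = int(counts.sum())
    target_total = int(target_total)
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds total count {total}")
    if target_total < 0:
        raise ValueError("target must be nonnegative")
    out = matrix.copy()
    if target_total == total:
        out.meta["downsampled_to"] = target_total
        return out
    if rng is None:
        rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(counts, target_total, method="marginals")
    keep = drawn > 0
    out.row, out.col, out.val = out.row[keep], out.col[keep], drawn[keep].astype(float)
    out.meta["downsampled_to"] = target_total
    out.meta["downsample_seed"] = seed
    return out


def ice_balance(matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                low_coverage_fraction: float = 0.02,
                include_diagonal: bool = True) -> tuple[ContactMatrix, BiasVector]:
    """Iterative correction: equalize per-bin marginals with multiplicative biases.

    Bins whose raw marginal is zero or below the ``low_coverage_fraction``
    quantile of positive marginals are masked.  Each iteration updates
    ``b_i <- b_i * m_i / mean(m)`` where ``m_i`` is the bias-corrected marginal
    of bin ``i``; iteration stops when the coefficient of variation of the
    unmasked marginals drops below ``tol`` or after ``max_iter`` rounds (the
    result is still returned, flagged non-converged).  Balanced values are
    ``raw_ij / (b_i * b_j)``, rescaled so the mean stored balanced value over
    unmasked bins is 1; entries touching masked bins are dropped.
    """
    n = matrix.nbins
    row, col = matrix.row, matrix.col
    val = matrix.val.astype(np.float64)
    diag = row == col
    if not include_diagonal:
        keep = ~diag
        row, col, val, diag = row[keep], col[keep], val[keep], diag[keep]

    def marginals(values: np.ndarray) -> np.ndarray:
        m = np.zeros(n)
        np.add.at(m, row, values)
        off = ~diag
        np.add.at(m, col[off], values[off])
        return m

    raw_marg = marginals(val)
    positive = raw_marg[raw_marg > 0]
    if positive.size == 0:
        raise ValueError("all bins have zero coverage; nothing to balance")
    thresh = np.quantile(positive, low_coverage_fraction) if low_coverage_fraction > 0 else 0.0
    mask = (raw_marg == 0) | (raw_marg < thresh)
    if mask.all():
        raise ValueError("all bins masked by the low-coverage filter")

    live = ~(mask[row] | mask[col])
    bias = np.ones(n)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = np.zeros_like(val)
        w[live] = val[live] / (bias[row[live]] * bias[col[live]])
        m = marginals(w)
        mu = m[~mask]
        mean = mu.mean()
        cv = mu.std() / mean if mean > 0 else np.inf
        if cv < tol:
            converged = True
            break
        bias[~mask] *= m[~mask] / mean
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations (cv above {tol}); "
            "returning the last iterate", RuntimeWarning)

    balanced = np.zeros_like(val)
    balanced[live] = val[live] / (bias[row[live]] * bias[col[live]])
    keep = live & (balanced > 0)
    bal_vals = balanced[keep]
    scale = bal_vals.mean() if bal_vals.size else 1.0
    bal_vals = bal_vals / scale
    bias = bias * np.sqrt(scale)

    bias_out = np.where(mask, np.nan, bias)
    out = ContactMatrix(
        matrix.bins, row[keep], col[keep], bal_vals, kind="balanced",
        mask=mask.copy(),
        meta={
            **matrix.meta,
            "ice_converged": converged,
            "ice_iterations": n_iter,
            "ice_tol": tol,
            "ice_low_coverage_fraction": low_coverage_fraction,
            "ice_include_diagonal": include_diagonal,
        },
    )
    return out, BiasVector(bias_out, mask)
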