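"""Readers and writers for the plain-text formats the toolkit consumes.

* chrom.sizes: two-column TSV (name, length)
* centromeres / annotations: BED (0-based, half-open after parsing)
* contact matrices: HiC-Pro-style sparse triplet ``.matrix`` plus companion
  bin ``.bed`` (triplet indices 1-based on disk by default, 0-based internally)
* loops / interactions: BEDPE
* tabular results: TSV
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import BinTable, GenomeModel
from .matrix import ContactMatrix

__all__ = [
    "AnnotationSet",
    "read_chrom_sizes",
    "read_centromeres_bed",
    "read_bed",
    "write_bed",
    "read_sparse_matrix",
    "write_sparse_matrix",
    "export_bedpe",
    "read_bedpe",
    "write_provenance",
    "read_provenance",
]


@dataclass
class AnnotationSet:
    """BED intervals: (chrom, start, end, name, score), half-open 0-based."""

    intervals: list[tuple[str, int, int, str, float]]

    def resolve(self, genome: GenomeModel) -> "AnnotationSet":
        lengths = genome.lengths
        for chrom, start, end, name, _ in self.intervals:
            if chrom not in lengths:
                raise ValueError(f"annotation chromosome {chrom!r} not in genome")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(
                    f"annotation {name!r} [{start}, {end}) outside {chrom}"
                )
        return self

    def __len__(self):
        return len(self.intervals)


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"],
                     comment="#")
    return [(str(c), int(l)) for c, l in zip(df["chrom"], df["length"])]


def read_bed(path) -> AnnotationSet:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            rows.append((chrom, start, end, name, score))
    return AnnotationSet(rows)


def write_bed(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score in annotations.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\n")


def read_centromeres_bed(path) -> dict[str, int]:
    """Centromere midpoints = centers of the BED intervals."""
    ann = read_bed(path)
    return {chrom: (start + end) // 2 for chrom, start, end, _, _ in ann.intervals}


# -- HiC-Pro-style sparse triplet matrices --------------------------------


def write_sparse_matrix(matrix: ContactMatrix, matrix_path, bins_path=None,
                        index_base: int = 1) -> None:
    """Write triplets (index1, index2, value) plus the companion bin BED."""
    fmt_int = matrix.is_integer()
    with open(matrix_path, "w") as fh:
        for i, j, v in zip(matrix.row, matrix.col, matrix.val):
            sval = f"{int(v)}" if fmt_int else f"{v:.10g}"
            fh.write(f"{i + index_base}\t{j + index_base}\t{sval}\n")
    if bins_path is not None:
        df = matrix.bins.to_dataframe()
        df["index"] = df["index"] + index_base
        df.to_csv(bins_path, sep="\t", header=False, index=False)


def _bin_table_from_bed(bins_path, index_base: int) -> BinTable:
    df = pd.read_csv(bins_path, sep=r"\s+", header=None,
                     names=["chrom", "start", "end", "index"], comment="#")
    df["index"] = df["index"] - index_base
    if not np.array_equal(df["index"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{bins_path}: bin indices not contiguous and 0-based "
                         f"after removing index base {index_base}")
    binsizes = (df["end"] - df["start"]).to_numpy()
    binsize = int(np.max(binsizes))
    chroms = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        expected = np.arange(len(sub)) * binsize
        if not np.array_equal(starts, expected):
            raise ValueError(f"{bins_path}: {chrom} bins are not a regular "
                             f"{binsize}-bp tiling from 0")
        chroms.append((str(chrom), int(sub["end"].iloc[-1])))
    return BinTable(GenomeModel(tuple(chroms)), binsize)


def read_sparse_matrix(matrix_path, bins_path=None, bin_table: Optional[BinTable] = None,
                       index_base: int = 1, kind: str = "raw") -> ContactMatrix:
    """Read a triplet matrix; entries are normalized to the upper triangle.

    Triplet indices on disk are 1-based by default (``index_base=1``) as
    written by HiC-Pro; pass ``index_base=0`` for 0-based files.  Duplicate
    coordinates after upper-triangle normalization are an error reported with
    the offending line numbers.
    """
    if bin_table is None:
        if bins_path is None:
            raise ValueError("either bins_path or bin_table is required")
        bin_table = _bin_table_from_bed(bins_path, index_base)

    rows, cols, vals = [], [], []
    with open(matrix_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{matrix_path}: line {ln}: expected 3 fields, "
                                 f"got {len(parts)}")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise ValueError(f"{matrix_path}: line {ln}: malformed triplet "
                                 f"{line!r}") from None
            if v < 0:
                raise ValueError(f"{matrix_path}: line {ln}: negative value {v}")
            i -= index_base
            j -= index_base
            if not (0 <= i < bin_table.nbins and 0 <= j < bin_table.nbins):
                raise ValueError(f"{matrix_path}: line {ln}: bin index outside "
                                 f"[0, {bin_table.nbins}) after base conversion")
            if i > j:
                i, j = j, i
            rows.append(i)
            cols.append(j)
            vals.append(v)
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    key = rows * bin_table.nbins + cols
    order = np.argsort(key, kind="stable")
    dup = np.nonzero(np.diff(key[order]) == 0)[0]
    if dup.size:
        lines = sorted({int(order[d]) + 1 for d in dup} | {int(order[d + 1]) + 1 for d in dup})
        raise ValueError(f"{matrix_path}: duplicate (i, j) coordinates at data "
                         f"lines {lines}")
    return ContactMatrix.from_entries(
        bin_table, rows, cols, np.asarray(vals), kind=kind, check=False
    )


# -- BEDPE ------------------------------------------------------------------


def export_bedpe(records: Iterable[tuple[int, int, str, float]],
                 bin_table: BinTable, path) -> None:
    """Write bin-pair interactions as BEDPE.

    ``records`` yields ``(bin_i, bin_j, name, score)`` with global bin indices;
    coordinates come from the bin table, 0-based half-open.  An empty input
    produces a valid file holding only the header comment.
    """
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\n")
        for bin_i, bin_j, name, score in records:
            for b in (bin_i, bin_j):
                if not (0 <= b < bin_table.nbins):
                    raise ValueError(f"bin index {b} out of range")
            c1 = bin_table.chrom_of(bin_i)
            c2 = bin_table.chrom_of(bin_j)
            s1, e1 = int(bin_table.bin_start(bin_i)), int(bin_table.bin_end(bin_i))
            s2, e2 = int(bin_table.bin_start(bin_j)), int(bin_table.bin_end(bin_j))
            fh.write(f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}\t{name}\t{score:.10g}\n")


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
               "name", "score"],
    )
    if len(df) == 0:
        df = df.astype({"start1": int, "end1": int, "start2": int, "end2": int})
    return df


# -- provenance --------------------------------------------------------------


def write_provenance(path, payload: dict) -> None:
    """Record the resolved parameters of a run next to its outputs."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_provenance(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
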