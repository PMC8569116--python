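"""Genome coordinate frame: chromosomes, point centromeres, and genome binning.

The budding-yeast genome is small enough (~12 Mb, 16 chromosomes) that a
contact matrix can be held in one global bin index space; per-chromosome views
are slices of that space.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeModel",
    "BinTable",
    "bin_genome",
    "locate_bin",
    "saccer3_genome",
    "demo_genome",
    "SACCER3_CHROM_SIZES",
    "SACCER3_CENTROMERE_MIDPOINTS",
]

# sacCer3 (R64-1-1) nuclear chromosome lengths in bp.
SACCER3_CHROM_SIZES: tuple[tuple[str, int], ...] = (
    ("chrI", 230218),
    ("chrII", 813184),
    ("chrIII", 316620),
    ("chrIV", 1531933),
    ("chrV", 576874),
    ("chrVI", 270161),
    ("chrVII", 1090940),
    ("chrVIII", 562643),
    ("chrIX", 439888),
    ("chrX", 745751),
    ("chrXI", 666816),
    ("chrXII", 1078177),
    ("chrXIII", 924431),
    ("chrXIV", 784333),
    ("chrXV", 1091291),
    ("chrXVI", 948066),
)

# Point-centromere midpoints, computed from the CEN1..CEN16 element coordinates
# (midpoint of the ~120-bp CDE element, 0-based).
_SACCER3_CEN_SPANS = {
    "chrI": (151465, 151582),
    "chrII": (238207, 238323),
    "chrIII": (114385, 114501),
    "chrIV": (449711, 449821),
    "chrV": (151987, 152104),
    "chrVI": (148510, 148627),
    "chrVII": (496920, 497038),
    "chrVIII": (105586, 105703),
    "chrIX": (355629, 355745),
    "chrX": (436307, 436425),
    "chrXI": (440129, 440246),
    "chrXII": (150828, 150947),
    "chrXIII": (268031, 268149),
    "chrXIV": (628758, 628875),
    "chrXV": (326584, 326702),
    "chrXVI": (555957, 556073),
}

SACCER3_CENTROMERE_MIDPOINTS: dict[str, int] = {
    name: (lo + hi) // 2 for name, (lo, hi) in _SACCER3_CEN_SPANS.items()
}


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names/lengths plus point-centromere midpoints.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres
        Map from chromosome name to centromere midpoint (bp).  May be empty
        for analyses that do not use centromeres.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has nonpositive length {length}")
        lengths = dict(self.chromosomes)
        for name, mid in self.centromeres.items():
            if name not in lengths:
                raise ValueError(f"centromere names unknown chromosome {name!r}")
            if not (0 <= mid < lengths[name]):
                raise ValueError(
                    f"centromere midpoint {mid} outside [0, {lengths[name]}) on {name}"
                )
        object.__setattr__(self, "chromosomes", tuple(tuple(c) for c in self.chromosomes))
        object.__setattr__(self, "centromeres", dict(self.centromeres))

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def centromere(self, chrom: str) -> int:
        if chrom not in self.centromeres:
            raise KeyError(f"no centromere annotated for {chrom!r}")
        return self.centromeres[chrom]

    def reorder(self, names: Sequence[str]) -> "GenomeModel":
        """Return the same genome with chromosomes listed in a new order."""
        lengths = self.lengths
        if sorted(names) != sorted(lengths):
            raise ValueError("reorder must use exactly the existing chromosome names")
        return GenomeModel(
            tuple((n, lengths[n]) for n in names),
            {n: m for n, m in self.centromeres.items()},
        )


def saccer3_genome() -> GenomeModel:
    """The bundled sacCer3 reference: 16 nuclear chromosomes + point centromeres."""
    return GenomeModel(SACCER3_CHROM_SIZES, SACCER3_CENTROMERE_MIDPOINTS)


def demo_genome() -> GenomeModel:
    """A small 4-chromosome genome with mid-arm centromeres, for fast tests."""
    chroms = (
        ("chrA", 200_000),
        ("chrB", 450_000),
        ("chrC", 700_000),
        ("chrD", 900_000),
    )
    cens = {"chrA": 80_000, "chrB": 170_000, "chrC": 300_000, "chrD": 400_000}
    return GenomeModel(chroms, cens)


class BinTable:
    """A fixed-width genome binning with one contiguous global index space.

    Bins are half-open ``[start, end)`` intervals; within a chromosome starts
    are ``0, binsize, 2*binsize, ...`` and the final partial bin is truncated
    at the chromosome end.  Global indices are 0-based and contiguous in
    genome order.
    """

    def __init__(self, genome: GenomeModel, binsize: int):
        if binsize < 1:
            raise ValueError(f"binsize must be >= 1, got {binsize}")
        self.genome = genome
        self.binsize = int(binsize)
        self._names = genome.names
        lengths = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
        self._nbins_per_chrom = -(-lengths // self.binsize)  # ceil division
        self._offsets = np.concatenate([[0], np.cumsum(self._nbins_per_chrom)])
        self._index = {n: i for i, n in enumerate(self._names)}

    @property
    def nbins(self) -> int:
        return int(self._offsets[-1])

    @property
    def chrom_names(self) -> list[str]:
        return list(self._names)

    def chrom_nbins(self, chrom: str) -> int:
        return int(self._nbins_per_chrom[self._index[chrom]])

    def chrom_offset(self, chrom: str) -> int:
        return int(self._offsets[self._index[chrom]])

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Global ``[lo, hi)`` index range of one chromosome's bins."""
        i = self._index[chrom]
        return int(self._offsets[i]), int(self._offsets[i + 1])

    def chrom_of(self, global_index: np.ndarray | int) -> np.ndarray | str:
        idx = np.searchsorted(self._offsets, np.asarray(global_index), side="right") - 1
        if np.isscalar(global_index) or np.ndim(global_index) == 0:
            return self._names[int(idx)]
        return np.array([self._names[i] for i in np.atleast_1d(idx)])

    def bin_start(self, global_index):
        gi = np.asarray(global_index, dtype=np.int64)
        ci = np.searchsorted(self._offsets, gi, side="right") - 1
        return (gi - self._offsets[ci]) * self.binsize

    def bin_end(self, global_index):
        gi = np.asarray(global_index, dtype=np.int64)
        ci = np.searchsorted(self._offsets, gi, side="right") - 1
        lengths = np.array([l for _, l in self.genome.chromosomes], dtype=np.int64)
        return np.minimum((gi - self._offsets[ci] + 1) * self.binsize, lengths[ci])

    def locate(self, chrom: str, pos: int) -> int:
        """Global index of the bin whose half-open interval contains ``pos``."""
        if chrom not in self._index:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = self.genome.length(chrom)
        if not (0 <= pos < length):
            raise ValueError(f"position {pos} out of range [0, {length}) on {chrom}")
        return self.chrom_offset(chrom) + int(pos) // self.binsize

    def same_binning(self, other: "BinTable") -> bool:
        return (
            self.binsize == other.binsize
            and self.genome.chromosomes == other.genome.chromosomes
        )

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for name, length in self.genome.chromosomes:
            n = self.chrom_nbins(name)
            starts = np.arange(n, dtype=np.int64) * self.binsize
            ends = np.minimum(starts + self.binsize, length)
            rows.append(
                pd.DataFrame({"chrom": name, "start": starts, "end": ends})
            )
        df = pd.concat(rows, ignore_index=True)
        df["index"] = np.arange(len(df), dtype=np.int64)
        return df

    def __len__(self) -> int:
        return self.nbins

    def __repr__(self) -> str:
        return f"BinTable({len(self._names)} chroms, binsize={self.binsize}, nbins={self.nbins})"


def bin_genome(genome: GenomeModel, binsize: int) -> BinTable:
    """Partition every chromosome into fixed-width half-open bins."""
    return BinTable(genome, binsize)


def locate_bin(bin_table: BinTable, chrom: str, pos: int) -> int:
    """Global bin index containing ``pos`` on ``chrom`` (half-open convention)."""
    return bin_table.locate(chrom, pos)
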