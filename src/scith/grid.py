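"""Genome bin grid: an ordered, non-overlapping tiling shared by all depth profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinGrid"]

#: chromosome names treated as sex chromosomes (excluded from "autosomal" views)
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class BinGrid:
    """Ordered half-open genomic bins, sorted by (chrom_order, start).

    Coordinates are 0-based half-open throughout.
    """

    chrom: np.ndarray  # str array, one entry per bin
    start: np.ndarray  # int array
    end: np.ndarray  # int array
    chrom_order: tuple = field(default=())

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=object)
        start = np.asarray(self.start, dtype=np.int64)
        end = np.asarray(self.end, dtype=np.int64)
        if not (len(chrom) == len(start) == len(end)):
            raise ValueError("chrom/start/end must have equal length")
        if np.any(end <= start):
            raise ValueError("bins must satisfy end > start")
        order = tuple(self.chrom_order) or tuple(pd.unique(chrom))
        rank = {c: i for i, c in enumerate(order)}
        try:
            key = np.array([rank[c] for c in chrom])
        except KeyError as exc:
            raise ValueError(f"chromosome {exc} missing from chrom_order") from exc
        if np.any(np.diff(key) < 0):
            raise ValueError("bins not sorted by chrom_order")
        for c in order:
            sel = chrom == c
            s, e = start[sel], end[sel]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] < e[:-1]):
                raise ValueError(f"bins on {c} overlap or are unsorted")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        object.__setattr__(self, "chrom_order", order)

    def __len__(self) -> int:
        return len(self.chrom)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )

    @property
    def widths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of bins on autosomes."""
        return np.array([c not in SEX_CHROMS for c in self.chrom])

    def chrom_slices(self) -> dict:
        """Map chromosome name -> slice of bin indices (bins are chrom-contiguous)."""
        out = {}
        for c in self.chrom_order:
            idx = np.flatnonzero(self.chrom == c)
            if idx.size:
                out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})

    def to_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "BinGrid":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
        )
        return cls(df["chrom"].to_numpy(object), df["start"].to_numpy(), df["end"].to_numpy())

    @classmethod
    def tile(cls, genome_spec, bin_size: int) -> "BinGrid":
        """Tile each chromosome into fixed-width bins; the last bin may be short."""
        if bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if not genome_spec:
            raise ValueError("genome_spec is empty")
        chroms, starts, ends = [], [], []
        for name, length in genome_spec:
            if length <= 0:
                raise ValueError(f"zero-length chromosome {name!r}")
            edges = np.arange(0, length, bin_size, dtype=np.int64)
            chroms.extend([name] * len(edges))
            starts.append(edges)
            ends.append(np.minimum(edges + bin_size, length))
        return cls(
            np.array(chroms, dtype=object),
            np.concatenate(starts),
            np.concatenate(ends),
            chrom_order=tuple(name for name, _ in genome_spec),
        )
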