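"""Genomic interval sets with BED semantics (0-based, half-open)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

__all__ = ["Interval", "RegionSet", "bins_overlapping"]


class Interval(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."


@dataclass
class RegionSet:
    """An ordered collection of stranded genomic intervals."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        checked = []
        for iv in self.intervals:
            iv = Interval(str(iv[0]), int(iv[1]), int(iv[2]), *iv[3:])
            if iv.start < 0 or iv.start >= iv.end:
                raise ValueError(f"invalid interval {iv.chrom}:{iv.start}-{iv.end}")
            if iv.strand not in ("+", "-", "."):
                raise ValueError(f"invalid strand {iv.strand!r}")
            checked.append(iv)
        self.intervals = checked

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sort(self) -> "RegionSet":
        return RegionSet(sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)))

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def lengths(self) -> np.ndarray:
        return np.array([iv.end - iv.start for iv in self.intervals], dtype=np.int64)

    def total_length(self) -> int:
        return int(self.lengths().sum()) if self.intervals else 0

    def on_chrom(self, chrom: str) -> "RegionSet":
        return RegionSet([iv for iv in self.intervals if iv.chrom == chrom])

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "RegionSet":
        return cls([Interval(*t) for t in tuples])


def bins_overlapping(
    regions: RegionSet, chrom: str, bin_size: int, n_bins: int, start_bp: int = 0
) -> np.ndarray:
    """Boolean per-bin vector: True where a bin overlaps >= 1 bp of a region."""
    hit = np.zeros(n_bins, dtype=bool)
    frame_end = start_bp + n_bins * bin_size
    for iv in regions:
        if iv.chrom != chrom or iv.end <= start_bp or iv.start >= frame_end:
            continue
        lo = max(iv.start - start_bp, 0) // bin_size
        hi = -(-(min(iv.end, frame_end) - start_bp) // bin_size)  # ceil div
        hit[lo:hi] = True
    return hit
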