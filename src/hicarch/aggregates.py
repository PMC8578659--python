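"""Domain and loop pileups with strength statistics.

Domain pileups take, for each domain of length L, the 3L-wide submap around
it and rescale it to a common 90x90 frame (area-weighted block averaging
when shrinking, bilinear interpolation when enlarging) before averaging over
domains.  Pixels 30..59 of the result correspond to the domain body, which
drives the within/between strength ratio.

Loop pileups average fixed-size (default 310 kb at 10 kb bins -> 31x31)
submaps centred on the anchor-pair bins; loop strength compares the 3x3
square at the loop base with the same square at the loop translated along
the diagonal by its own length in each direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hicarch.matrix import ContactMatrix
from hicarch.regions import RegionSet

__all__ = [
    "AggregateMap",
    "LoopAnchors",
    "rescale_map",
    "tad_aggregate",
    "tad_strength",
    "loop_aggregate",
    "loop_strength",
]

TAD_MAP_SIZE = 90
LOOP_WINDOW_BP = 310_000
LOOP_SQUARE_BINS = 3  # "31 x 31 kb square" at 10 kb bins: base bin +/- 1


@dataclass
class AggregateMap:
    """Averaged submap with per-cell contributor counts."""

    values: np.ndarray
    n_elements: np.ndarray
    kind: str  # {tad, loop, boundary}
    n_used: int = 0
    n_skipped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("tad", "loop", "boundary"):
            raise ValueError(f"unknown aggregate kind {self.kind!r}")


@dataclass
class LoopAnchors:
    """Anchor pairs (a < b, same chromosome), midpoints in bp."""

    chrom: str
    pairs: list[tuple[int, int]]

    def __post_init__(self):
        for a, b in self.pairs:
            if not a < b:
                raise ValueError("loop anchors must satisfy a < b")

    def __len__(self):
        return len(self.pairs)

    @classmethod
    def from_intervals(cls, chrom: str, anchors: list[tuple]) -> "LoopAnchors":
        """Build from ((start1, end1), (start2, end2)) interval pairs."""
        pairs = []
        for (s1, e1), (s2, e2) in anchors:
            a, b = (s1 + e1) // 2, (s2 + e2) // 2
            if a > b:
                a, b = b, a
            pairs.append((a, b))
        return cls(chrom, pairs)


def _block_average(src: np.ndarray, out_size: int) -> np.ndarray:
    """Area-weighted mean over fractional source blocks (exact for shrinking)."""
    n = src.shape[0]
    scale = n / out_size
    # weight matrix W[t, s] = overlap of target cell t with source cell s
    w = np.zeros((out_size, n))
    for t in range(out_size):
        lo, hi = t * scale, (t + 1) * scale
        s0, s1 = int(np.floor(lo)), int(np.ceil(hi))
        for s in range(s0, min(s1, n)):
            w[t, s] = min(hi, s + 1) - max(lo, s)
    w /= w.sum(axis=1, keepdims=True)
    filled = np.where(np.isfinite(src), src, 0.0)
    ok = np.isfinite(src).astype(float)
    num = w @ filled @ w.T
    den = w @ ok @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _bilinear(src: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear interpolation on bin centres (for enlarging)."""
    n = src.shape[0]
    centers_src = np.arange(n) + 0.5
    centers_out = (np.arange(out_size) + 0.5) * n / out_size
    x = np.clip(centers_out, centers_src[0], centers_src[-1])
    i0 = np.clip(np.searchsorted(centers_src, x) - 1, 0, n - 2)
    frac = (x - centers_src[i0]) / 1.0
    rows = src[i0] * (1 - frac)[:, None] + src[i0 + 1] * frac[:, None]
    cols = rows[:, i0] * (1 - frac)[None, :] + rows[:, i0 + 1] * frac[None, :]
    return cols


def rescale_map(src: np.ndarray, out_size: int = TAD_MAP_SIZE) -> np.ndarray:
    """Resample a square map to ``out_size`` per side.

    Block-averaging (mean-preserving on block-constant inputs) when the
    source is at least as large as the target; bilinear interpolation on bin
    centres when smaller.  Identity when sizes match.
    """
    if src.shape[0] != src.shape[1]:
        raise ValueError("rescale_map expects a square map")
    if src.shape[0] == out_size:
        return src.copy()
    if src.shape[0] > out_size:
        return _block_average(src, out_size)
    return _bilinear(src, out_size)


def tad_aggregate(oe: ContactMatrix, tads: RegionSet) -> AggregateMap:
    """Average rescaled 3L-windows over domains.

    Domains shorter than 3 bins, on another chromosome, or whose extended
    window leaves the matrix are skipped and counted.
    """
    if oe.kind != "oe":
        raise ValueError("tad_aggregate expects an O/E matrix")
    size = TAD_MAP_SIZE
    total = np.zeros((size, size))
    n_cell = np.zeros((size, size), dtype=np.int64)
    used = skipped = 0
    for iv in tads:
        if iv.chrom != oe.chrom:
            skipped += 1
            continue
        length = iv.end - iv.start
        lo_bin = oe.bin_of(iv.start - length)
        hi_bin = oe.bin_of(iv.end + length - 1) + 1
        if (iv.end - iv.start) // oe.bin_size < 3:
            skipped += 1
            continue
        if lo_bin < 0 or hi_bin > oe.n_bins:
            skipped += 1
            continue
        sub = oe.values[lo_bin:hi_bin, lo_bin:hi_bin]
        scaled = rescale_map(sub, size)
        ok = np.isfinite(scaled)
        total[ok] += scaled[ok]
        n_cell += ok
        used += 1
    if used == 0:
        raise ValueError("no usable domains for aggregation")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_cell > 0, total / np.maximum(n_cell, 1), np.nan)
    return AggregateMap(values, n_cell, "tad", n_used=used, n_skipped=skipped)


def tad_strength(a: AggregateMap) -> float:
    """Within/between intensity ratio of a 90x90 domain pileup.

    Numerator: sum of rows 30..59 x columns 30..59.  Denominator: half the
    sum of blocks [0:30, 30:60] and [30:60, 60:90] (0-based, half-open).
    """
    v = a.values
    if v.shape != (TAD_MAP_SIZE, TAD_MAP_SIZE):
        raise ValueError("tad_strength expects a 90x90 map")
    within = np.nansum(v[30:60, 30:60])
    between = 0.5 * (np.nansum(v[0:30, 30:60]) + np.nansum(v[30:60, 60:90]))
    if between == 0:
        raise ValueError("zero between-domain intensity")
    return float(within / between)


def loop_aggregate(
    oe10: ContactMatrix, loops: LoopAnchors, window_bp: int = LOOP_WINDOW_BP
) -> AggregateMap:
    """Average fixed-size submaps centred on loop anchor-pair bins."""
    if oe10.kind != "oe":
        raise ValueError("loop_aggregate expects an O/E matrix")
    if loops.chrom != oe10.chrom:
        raise ValueError("loops are on a different chromosome than the matrix")
    half = (int(window_bp) // oe10.bin_size) // 2
    side = 2 * half + 1
    total = np.zeros((side, side))
    n_cell = np.zeros((side, side), dtype=np.int64)
    used = skipped = 0
    for a, b in loops.pairs:
        ia, ib = oe10.bin_of(a), oe10.bin_of(b)
        if ia - half < 0 or ib + half >= oe10.n_bins or ib - half < 0 or ia + half >= oe10.n_bins:
            skipped += 1
            continue
        sub = oe10.values[ia - half : ia + half + 1, ib - half : ib + half + 1]
        ok = np.isfinite(sub)
        total[ok] += sub[ok]
        n_cell += ok
        used += 1
    if used == 0:
        raise ValueError("no usable loops for aggregation")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_cell > 0, total / np.maximum(n_cell, 1), np.nan)
    return AggregateMap(values, n_cell, "loop", n_used=used, n_skipped=skipped)


def _square_mean(v: np.ndarray, i: int, j: int, half: int) -> float:
    n = v.shape[0]
    if i - half < 0 or j - half < 0 or i + half >= n or j + half >= n:
        return np.nan
    sq = v[i - half : i + half + 1, j - half : j + half + 1]
    sq = sq[np.isfinite(sq)]
    return float(sq.mean()) if sq.size else np.nan


def loop_strength(oe10: ContactMatrix, loops: LoopAnchors) -> float:
    """Mean over loops of base-square O/E over offset-square O/E.

    For each loop (a, b) the numerator is the mean over the 3x3-bin square at
    (bin(a), bin(b)); the denominator averages the same square at the two
    diagonal translations by the loop length, (a-L, b-L) and (a+L, b+L),
    using whichever lies on the matrix.  Loops with no usable offset are
    skipped.
    """
    if oe10.kind != "oe":
        raise ValueError("loop_strength expects an O/E matrix")
    half = LOOP_SQUARE_BINS // 2
    ratios = []
    for a, b in loops.pairs:
        ia, ib = oe10.bin_of(a), oe10.bin_of(b)
        span = ib - ia
        base = _square_mean(oe10.values, ia, ib, half)
        offs = [
            _square_mean(oe10.values, ia - span, ib - span, half),
            _square_mean(oe10.values, ia + span, ib + span, half),
        ]
        offs = [o for o in offs if np.isfinite(o)]
        if not np.isfinite(base) or not offs:
            continue
        den = float(np.mean(offs))
        if den > 0:
            ratios.append(base / den)
    if not ratios:
        raise ValueError("no loops with usable offset controls")
    return float(np.mean(ratios))
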