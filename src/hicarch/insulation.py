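"""Insulation score with local normalization, and oriented boundary pileups."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hicarch.matrix import ContactMatrix
from hicarch.regions import RegionSet

__all__ = ["InsulationTrack", "insulation_score", "call_boundaries", "boundary_aggregate"]

DEFAULT_WINDOW_BINS = 5
NORMALIZATION_SPAN = 50  # bins centred on i used for the local mean


@dataclass
class InsulationTrack:
    """Raw and normalized insulation per bin.

    ``raw[i]`` is the mean O/E over the square window with rows
    ``i-w .. i-1`` and columns ``i+1 .. i+w`` (w = ``window_bins``);
    ``normalized[i]`` is log2 of raw over the mean raw of the nearest
    :data:`NORMALIZATION_SPAN` bins centred on ``i`` (truncated at the track
    ends).  Both are NaN where the window leaves the matrix or is empty.
    """

    chrom: str
    bin_size: int
    raw: np.ndarray
    normalized: np.ndarray
    window_bins: int
    start_bp: int = 0

    @property
    def n_bins(self) -> int:
        return self.raw.shape[0]


def insulation_score(
    oe: ContactMatrix, window_bins: int = DEFAULT_WINDOW_BINS
) -> InsulationTrack:
    if oe.kind != "oe":
        raise ValueError("insulation_score expects an O/E matrix")
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    n = oe.n_bins
    w = window_bins
    v = np.where(np.isfinite(oe.values), oe.values, np.nan)
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        window = v[i - w : i, i + 1 : i + w + 1]
        if np.isfinite(window).any():
            raw[i] = np.nanmean(window)
    normalized = np.full(n, np.nan)
    half = NORMALIZATION_SPAN // 2
    for i in range(n):
        if not np.isfinite(raw[i]):
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        local = raw[lo:hi]
        local = local[np.isfinite(local)]
        if local.size and local.mean() > 0 and raw[i] > 0:
            normalized[i] = np.log2(raw[i] / local.mean())
    return InsulationTrack(oe.chrom, oe.bin_size, raw, normalized, w, start_bp=oe.start_bp)


def call_boundaries(track: InsulationTrack) -> np.ndarray:
    """Bins that are local minima of the normalized insulation.

    Plateau minima (runs of equal values flanked by higher neighbours) are
    reported in full; a strict dip on at least one side is required.
    """
    s = track.normalized
    idx = []
    for i in range(1, track.n_bins - 1):
        if not np.isfinite(s[i]):
            continue
        left = s[i - 1] if np.isfinite(s[i - 1]) else np.inf
        right = s[i + 1] if np.isfinite(s[i + 1]) else np.inf
        if s[i] <= left and s[i] <= right and (s[i] < left or s[i] < right):
            idx.append(i)
    return np.array(idx, dtype=np.int64)


def _five_prime_bin(iv, m: ContactMatrix) -> int:
    # minus-strand elements have their 5' end at the interval end
    pos = iv.start if iv.strand != "-" else iv.end - 1
    return m.bin_of(pos)


def boundary_aggregate(
    oe: ContactMatrix,
    elements: RegionSet,
    flank_bp: int = 1_000_000,
    zscore_rows: bool = False,
):
    """Average the O/E neighbourhood of oriented elements.

    Extracts, for each element, the square submap centred on the bin holding
    its 5' end with ``flank_bp`` of flank on each side; minus-strand submaps
    are flipped along both axes before averaging, so the aggregate is in
    5'->3' orientation.  Elements whose window leaves the matrix are skipped.

    Returns an :class:`~hicarch.aggregates.AggregateMap` of kind
    ``boundary``.  With ``zscore_rows`` the log2 aggregate is z-scored across
    each row (constant rows stay NaN).
    """
    from hicarch.aggregates import AggregateMap  # local import, avoids cycle

    if oe.kind != "oe":
        raise ValueError("boundary_aggregate expects an O/E matrix")
    flank_bins = int(flank_bp) // oe.bin_size
    side = 2 * flank_bins + 1
    total = np.zeros((side, side))
    n_cell = np.zeros((side, side), dtype=np.int64)
    used = skipped = 0
    for iv in elements:
        if iv.chrom != oe.chrom:
            skipped += 1
            continue
        c = _five_prime_bin(iv, oe)
        if c - flank_bins < 0 or c + flank_bins >= oe.n_bins:
            skipped += 1
            continue
        sub = oe.values[
            c - flank_bins : c + flank_bins + 1, c - flank_bins : c + flank_bins + 1
        ]
        if iv.strand == "-":
            sub = sub[::-1, ::-1]
        ok = np.isfinite(sub)
        total[ok] += sub[ok]
        n_cell += ok
        used += 1
    if used == 0:
        raise ValueError("no usable elements for boundary aggregation")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_cell > 0, total / np.maximum(n_cell, 1), np.nan)
        if zscore_rows:
            logv = np.log2(np.where(values > 0, values, np.nan))
            mu = np.nanmean(logv, axis=1, keepdims=True)
            sd = np.nanstd(logv, axis=1, keepdims=True)
            values = np.where(sd > 0, (logv - mu) / sd, np.nan)
    return AggregateMap(values=values, n_elements=n_cell, kind="boundary",
                        n_used=used, n_skipped=skipped)
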