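"""A/B compartment profile, saddle enrichment map and compartment strength.

The pipeline is: correlation matrix -> leading principal component
(:func:`compute_pc1`) -> sign orientation against a GC track
(:func:`orient_by_gc`) -> five-quantile saddle map of averaged O/E values
(:func:`saddle`) -> scalar strength ln((AA*BB)/AB^2) with an optional
per-pixel bootstrap (:func:`compartment_strength`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hicarch.matrix import ContactMatrix, GenomeTrack

__all__ = [
    "SaddleMap",
    "CompartmentStrength",
    "compute_pc1",
    "orient_by_gc",
    "saddle",
    "compartment_strength",
]

N_QUANTILES = 5


@dataclass
class SaddleMap:
    """5x5 map of averaged O/E between PC1-quintile bin groups.

    ``contributors[a][b]`` keeps the raw O/E values averaged into cell
    ``(a, b)`` so that strength bootstraps can resample them per pixel.
    """

    values: np.ndarray
    bin_edges: np.ndarray
    n_pairs: np.ndarray
    contributors: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if self.values.shape != (N_QUANTILES, N_QUANTILES):
            raise ValueError("saddle map must be 5x5")


@dataclass
class CompartmentStrength:
    strength: float
    AA: float
    BB: float
    AB: float
    bootstrap: np.ndarray | None = None

    def bootstrap_std(self) -> float:
        if self.bootstrap is None:
            raise ValueError("no bootstrap samples stored")
        return float(np.std(self.bootstrap, ddof=1))


def compute_pc1(pcc: ContactMatrix) -> GenomeTrack:
    """Leading principal-component loading of the correlation matrix.

    Columns of the unmasked correlation submatrix are centered and the unit
    eigenvector of the largest eigenvalue of the column covariance is
    returned, one value per bin (NaN on masked/undefined bins).  The global
    sign is arbitrary; see :func:`orient_by_gc`.
    """
    if pcc.kind != "pcc":
        raise ValueError("compute_pc1 expects a correlation (pcc) matrix")
    keep = ~pcc.mask & np.isfinite(pcc.values).any(axis=0)
    if keep.sum() < 3:
        raise ValueError("need at least 3 defined bins for PC1")
    sub = pcc.values[np.ix_(keep, keep)]
    sub = np.where(np.isfinite(sub), sub, 0.0)
    centered = sub - sub.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / max(centered.shape[0] - 1, 1)
    if not np.any(np.abs(cov) > 1e-12):
        raise ValueError("correlation matrix has zero variance; PC1 undefined")
    evals, evecs = np.linalg.eigh(cov)
    lead = evecs[:, -1]
    lead = lead / np.linalg.norm(lead)
    out = np.full(pcc.n_bins, np.nan)
    out[keep] = lead
    return GenomeTrack(pcc.chrom, pcc.bin_size, out, start_bp=pcc.start_bp)


def orient_by_gc(pc1: GenomeTrack, gc: GenomeTrack) -> GenomeTrack:
    """Flip PC1 sign so positive entries have the higher mean GC content.

    Positive PC1 is then read as the A compartment.  If all defined entries
    share one sign the track is returned unchanged.  Applying the operation
    twice equals applying it once.
    """
    if pc1.n_bins != gc.n_bins:
        raise ValueError("PC1 and GC tracks must have equal length")
    v = pc1.values
    ok = np.isfinite(v) & np.isfinite(gc.values)
    pos = ok & (v > 0)
    neg = ok & (v < 0)
    if not pos.any() or not neg.any():
        return GenomeTrack(pc1.chrom, pc1.bin_size, v.copy(), start_bp=pc1.start_bp)
    if gc.values[neg].mean() > gc.values[pos].mean():
        v = -v
    return GenomeTrack(pc1.chrom, pc1.bin_size, v.copy(), start_bp=pc1.start_bp)


def quantile_assignments(pc1_values: np.ndarray, defined: np.ndarray) -> np.ndarray:
    """Assign defined bins to five PC1 quantile groups (0 = lowest).

    Edges are the 20/40/60/80th percentiles of the defined values; a value
    equal to an edge joins the higher group.  Undefined bins get -1.
    """
    q = np.full(pc1_values.shape[0], -1, dtype=np.int64)
    vals = pc1_values[defined]
    edges = np.percentile(vals, [20, 40, 60, 80])
    q[defined] = np.clip(np.searchsorted(edges, vals, side="right"), 0, N_QUANTILES - 1)
    return q


def saddle(oe: ContactMatrix, pc1: GenomeTrack, keep_contributors: bool = True) -> SaddleMap:
    """Average O/E values between bins grouped by PC1 quintile.

    Cell (a, b) is the mean over all defined entry pairs (i, j) with bin i in
    quintile a and bin j in quintile b; both orientations of each unordered
    pair contribute, so the map is symmetric.
    """
    if oe.kind != "oe":
        raise ValueError("saddle expects an O/E matrix")
    if pc1.n_bins != oe.n_bins:
        raise ValueError("PC1 track does not match the matrix frame")
    defined = ~oe.mask & np.isfinite(pc1.values)
    if defined.sum() < N_QUANTILES:
        raise ValueError("need at least 5 defined bins for a saddle map")
    q = quantile_assignments(pc1.values, defined)
    edges = np.concatenate(
        (
            [np.min(pc1.values[defined])],
            np.percentile(pc1.values[defined], [20, 40, 60, 80]),
            [np.max(pc1.values[defined])],
        )
    )
    values = np.full((N_QUANTILES, N_QUANTILES), np.nan)
    n_pairs = np.zeros((N_QUANTILES, N_QUANTILES), dtype=np.int64)
    contributors: list[list[np.ndarray]] = [
        [np.empty(0) for _ in range(N_QUANTILES)] for _ in range(N_QUANTILES)
    ]
    idx_by_q = [np.nonzero(q == g)[0] for g in range(N_QUANTILES)]
    for a in range(N_QUANTILES):
        for b in range(a, N_QUANTILES):
            block = oe.values[np.ix_(idx_by_q[a], idx_by_q[b])]
            vals = block[np.isfinite(block)]
            if vals.size:
                values[a, b] = values[b, a] = vals.mean()
            n_pairs[a, b] = n_pairs[b, a] = vals.size
            if keep_contributors:
                contributors[a][b] = vals
                contributors[b][a] = vals
    return SaddleMap(values, edges, n_pairs, contributors if keep_contributors else None)


def _strength_from_map(v: np.ndarray) -> tuple[float, float, float, float]:
    # AA: quintile rows/cols 1-3 (1-indexed), BB: 3-5; the middle quintile is
    # shared by both blocks, exactly as defined. AB averages the two
    # symmetric off-blocks.
    aa = float(np.nansum(v[0:3, 0:3]))
    bb = float(np.nansum(v[2:5, 2:5]))
    ab = float(np.nansum(v[0:3, 2:5]) + np.nansum(v[2:5, 0:3])) / 2.0
    if ab <= 0:
        raise ValueError("degenerate saddle: AB block sum is zero")
    return float(np.log((aa * bb) / ab**2)), aa, bb, ab


def compartment_strength(
    s: SaddleMap, n_boot: int = 0, seed: int = 0
) -> CompartmentStrength:
    """Compartment strength ln((AA*BB)/AB^2) with optional per-pixel bootstrap.

    Each bootstrap replicate resamples, with replacement and at the original
    size, the O/E values that contributed to every saddle pixel, then
    recomputes the strength from the resampled map.
    """
    strength, aa, bb, ab = _strength_from_map(s.values)
    boot = None
    if n_boot > 0:
        if s.contributors is None:
            raise ValueError("saddle map has no stored contributors to bootstrap")
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for r in range(n_boot):
            v = np.full((N_QUANTILES, N_QUANTILES), np.nan)
            for a in range(N_QUANTILES):
                for b in range(a, N_QUANTILES):
                    vals = s.contributors[a][b]
                    if vals.size:
                        res = vals[rng.integers(0, vals.size, size=vals.size)]
                        v[a, b] = v[b, a] = res.mean()
            boot[r], *_ = _strength_from_map(v)
    return CompartmentStrength(strength, aa, bb, ab, bootstrap=boot)
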