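"""Planted-structure generators for contact matrices and expression tables.

The contact generator composes a power-law distance-decay expectation with
multiplicative factors for planted compartments, domains, loops, a
high-contact block ("hub") and a focal locus with condition-specific
contacts to that block, then draws Poisson counts.  Planted coordinates are
returned as ground truth so every downstream statistic has a
parameter-recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hicarch.matrix import ContactMatrix, GenomeTrack
from hicarch.stages import ExpressionMatrix

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "block_labels",
    "simulate_hic",
    "simulate_expression",
]

GC_BASELINE = 0.40
GC_A_DELTA = 0.05


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cis contact map.

    Contrasts are O/E ratios: ``compartment_contrast`` is the within- over
    between-compartment contact ratio; domain, loop, hub and focal factors
    multiply the decay expectation on their footprints.
    """

    n_bins: int = 600
    bin_size: int = 150_000
    chrom: str = "chrS"
    decay_exponent: float = 1.0
    compartment_labels: np.ndarray | None = None  # +1 (A) / -1 (B) per bin
    compartment_contrast: float = 1.0
    tads: list[tuple[int, int, float]] = field(default_factory=list)  # (start_bin, end_bin, contrast)
    loops: list[tuple[int, int, float]] = field(default_factory=list)  # (bin_a, bin_b, enrichment)
    hub_bins: np.ndarray | None = None
    hub_contrast: float = 1.0
    focal_bins: np.ndarray | None = None
    focal_hub_contrast: float = 1.0
    depth: float = 2e6
    seed: int = 0

    def validate(self) -> None:
        if self.n_bins < 2 or self.bin_size <= 0:
            raise ValueError("invalid matrix frame")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for c in (self.compartment_contrast, self.hub_contrast, self.focal_hub_contrast):
            if c <= 0:
                raise ValueError("contrasts must be positive")
        if self.compartment_labels is not None:
            lab = np.asarray(self.compartment_labels)
            if lab.shape != (self.n_bins,) or not np.isin(lab, (-1, 1)).all():
                raise ValueError("compartment labels must be +/-1 per bin")
        for s, e, c in self.tads:
            if not (0 <= s < e <= self.n_bins) or c <= 0:
                raise ValueError(f"invalid domain ({s}, {e}, {c})")
        for a, b, c in self.loops:
            if not (0 <= a < b < self.n_bins) or c <= 0:
                raise ValueError(f"invalid loop ({a}, {b}, {c})")
        for bins in (self.hub_bins, self.focal_bins):
            if bins is not None:
                bins = np.asarray(bins)
                if bins.size and (bins.min() < 0 or bins.max() >= self.n_bins):
                    raise ValueError("feature bins outside matrix bounds")


@dataclass
class GroundTruth:
    compartment_labels: np.ndarray | None
    boundaries: np.ndarray  # TAD start/end bins
    tads: list[tuple[int, int, float]]
    loops: list[tuple[int, int, float]]
    hub_bins: np.ndarray | None
    focal_bins: np.ndarray | None
    expression_clusters: pd.Series | None = None


def block_labels(n_bins: int, block_bins: int, seed: int | None = None) -> np.ndarray:
    """Alternating +/-1 compartment blocks; with a seed, block sizes jitter."""
    labels = np.empty(n_bins, dtype=np.int64)
    rng = np.random.default_rng(seed) if seed is not None else None
    sign, i = 1, 0
    while i < n_bins:
        size = block_bins
        if rng is not None:
            size = max(2, int(rng.integers(block_bins // 2, block_bins * 3 // 2 + 1)))
        labels[i : i + size] = sign
        sign = -sign
        i += size
    return labels


def random_contiguous_tads(
    n_bins: int,
    seed: int,
    min_bins: int = 15,
    max_bins: int = 30,
    margin: int = 10,
    contrast: float = 2.0,
) -> list[tuple[int, int, float]]:
    """Adjacent domains tiling the matrix interior, sharing boundaries."""
    rng = np.random.default_rng(seed)
    edges = [margin]
    while edges[-1] + max_bins <= n_bins - margin:
        edges.append(edges[-1] + int(rng.integers(min_bins, max_bins + 1)))
    return [(a, b, contrast) for a, b in zip(edges, edges[1:])]


def expected_matrix(spec: SimulationSpec) -> np.ndarray:
    """Noise-free expectation, scaled so upper-triangle total equals depth."""
    spec.validate()
    n = spec.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = np.maximum(d, 1).astype(float) ** (-spec.decay_exponent)
    if spec.compartment_labels is not None and spec.compartment_contrast != 1.0:
        lab = np.asarray(spec.compartment_labels)
        same = np.equal.outer(lab, lab)
        root = np.sqrt(spec.compartment_contrast)
        e *= np.where(same, root, 1.0 / root)
    for s, t, c in spec.tads:
        e[s:t, s:t] *= c
    for a, b, c in spec.loops:
        lo_a, hi_a = max(a - 1, 0), min(a + 2, n)
        lo_b, hi_b = max(b - 1, 0), min(b + 2, n)
        e[lo_a:hi_a, lo_b:hi_b] *= c
        e[lo_b:hi_b, lo_a:hi_a] *= c
    if spec.hub_bins is not None and spec.hub_contrast != 1.0:
        hb = np.asarray(spec.hub_bins)
        e[np.ix_(hb, hb)] *= spec.hub_contrast
    if (
        spec.focal_bins is not None
        and spec.hub_bins is not None
        and spec.focal_hub_contrast != 1.0
    ):
        fb = np.asarray(spec.focal_bins)
        hb = np.asarray(spec.hub_bins)
        e[np.ix_(fb, hb)] *= spec.focal_hub_contrast
        e[np.ix_(hb, fb)] *= spec.focal_hub_contrast
    e = (e + e.T) / 2.0
    total = np.triu(e).sum()
    return e * (spec.depth / total)


def simulate_hic(spec: SimulationSpec) -> tuple[ContactMatrix, GroundTruth, GenomeTrack]:
    """Draw a Poisson contact map around the planted expectation.

    Counts are sampled on the upper triangle and mirrored, so the matrix is
    exactly symmetric; the run is deterministic for a fixed spec seed.  The
    GC track is higher on A-labelled bins, supporting sign orientation.
    """
    e = expected_matrix(spec)
    n = spec.n_bins
    rng = np.random.default_rng(spec.seed)
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(e[iu])
    counts = counts + counts.T - np.diag(np.diag(counts))
    m = ContactMatrix(spec.chrom, spec.bin_size, counts, kind="raw")
    gc = np.full(n, GC_BASELINE)
    if spec.compartment_labels is not None:
        gc = gc + GC_A_DELTA * (np.asarray(spec.compartment_labels) > 0)
    truth = GroundTruth(
        compartment_labels=(
            np.asarray(spec.compartment_labels).copy()
            if spec.compartment_labels is not None
            else None
        ),
        boundaries=np.unique([b for s, t, _ in spec.tads for b in (s, t)]),
        tads=list(spec.tads),
        loops=list(spec.loops),
        hub_bins=None if spec.hub_bins is None else np.asarray(spec.hub_bins).copy(),
        focal_bins=None if spec.focal_bins is None else np.asarray(spec.focal_bins).copy(),
    )
    return m, truth, GenomeTrack(spec.chrom, spec.bin_size, gc)


def simulate_expression(
    n_genes_per_cluster: int,
    stages: list[str],
    noise_sd: float,
    treatment_shift: list[float],
    seed: int = 0,
    peak_tpm: float = 100.0,
    baseline_tpm: float = 0.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Stage-patterned expression with planted clusters and treatment shifts.

    Cluster ``g`` genes peak at stage ``g`` (clusters cycle through stages if
    there are more clusters than stages).  Multiplicative log-normal noise
    (sd in log2 units) perturbs the control profile; the treated table shifts
    each cluster by ``treatment_shift[g]`` in log2(TPM+1) units.
    """
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    k = len(treatment_shift)
    rng = np.random.default_rng(seed)
    n_stages = len(stages)
    rows, labels = [], []
    for g in range(k):
        peak_stage = g % n_stages
        base = np.full(n_stages, baseline_tpm)
        base[peak_stage] = peak_tpm
        noise = rng.normal(0.0, noise_sd, size=(n_genes_per_cluster, n_stages))
        rows.append(base[None, :] * 2.0**noise)
        labels.extend([f"C{g + 1}"] * n_genes_per_cluster)
    genes = [f"gene{i:05d}" for i in range(k * n_genes_per_cluster)]
    control = pd.DataFrame(np.vstack(rows), index=genes, columns=stages)
    shift_per_gene = np.repeat(np.asarray(treatment_shift, float), n_genes_per_cluster)
    treated = 2.0 ** (np.log2(control + 1.0).add(shift_per_gene, axis=0)) - 1.0
    treated = treated.clip(lower=0.0)
    truth = GroundTruth(
        compartment_labels=None,
        boundaries=np.empty(0, dtype=np.int64),
        tads=[],
        loops=[],
        hub_bins=None,
        focal_bins=None,
        expression_clusters=pd.Series(labels, index=genes, name="cluster"),
    )
    return (
        ExpressionMatrix(control),
        ExpressionMatrix(treated),
        truth,
    )
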