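"""Region-set contact enrichment against random-region nulls.

Implements the comparison framework used for peri-nucleolar-heterochromatin
style analyses: per-pair contact (or correlation) values within a region
set, or between a focal locus and a region set, tested against N random
region sets of matched number and length with a two-sided Mann-Whitney U
test per replicate, the replicate p-values averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hicarch.matrix import ContactMatrix
from hicarch.regions import Interval, RegionSet, bins_overlapping

__all__ = [
    "EnrichmentResult",
    "contacts_within",
    "contacts_between",
    "sample_random_regions",
    "mann_whitney_u",
    "enrichment_test",
    "pcc_difference",
    "contacts_log2fc",
]

EXACT_PRODUCT_LIMIT = 400  # exact MWU when n*m <= this and no ties
_MIN_P = float(np.finfo(float).tiny)  # never report p = 0


@dataclass
class EnrichmentResult:
    observed_values: np.ndarray
    null_values: list[np.ndarray]
    u_stats: np.ndarray
    p_values: np.ndarray
    p_mean: float
    n_replicates: int
    seed: int
    direction: str = ""  # "enriched" | "depleted" | "none"
    observed_mean: float = float("nan")
    null_means: np.ndarray = field(default_factory=lambda: np.empty(0))


def _in_set_bins(m: ContactMatrix, regions: RegionSet) -> np.ndarray:
    hit = bins_overlapping(regions, m.chrom, m.bin_size, m.n_bins, m.start_bp)
    return hit & ~m.mask


def contacts_within(m: ContactMatrix, regions: RegionSet) -> np.ndarray:
    """Defined values of all pairs (i < j) with both bins in the region set."""
    bins = np.nonzero(_in_set_bins(m, regions))[0]
    if bins.size < 2:
        raise ValueError("need at least 2 in-set bins")
    sub = m.values[np.ix_(bins, bins)]
    iu = np.triu_indices(bins.size, k=1)
    vals = sub[iu]
    return vals[np.isfinite(vals)]


def contacts_between(
    m: ContactMatrix, focal: RegionSet, regions: RegionSet
) -> np.ndarray:
    """Defined values of pairs with one bin in the focal set, one in the
    region set, excluding pairs internal to the focal set."""
    fbins = _in_set_bins(m, focal)
    rbins = _in_set_bins(m, regions)
    if not fbins.any() or not (rbins & ~fbins).any():
        raise ValueError("focal and region sets leave no usable bin pairs")
    fi = np.nonzero(fbins)[0]
    ri = np.nonzero(rbins & ~fbins)[0]
    vals = m.values[np.ix_(fi, ri)].ravel()
    return vals[np.isfinite(vals)]


def sample_random_regions(
    template: RegionSet,
    chrom_sizes: dict[str, int],
    n_replicates: int,
    seed: int,
    masked_bp: RegionSet | None = None,
    max_retries: int = 1000,
) -> list[RegionSet]:
    """Random region sets matching the template's number and length multiset.

    Each interval is re-placed uniformly on its own chromosome, keeping the
    intervals of one replicate non-overlapping and clear of ``masked_bp``
    regions.  Deterministic for a fixed seed.
    """
    for iv in template:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {iv.chrom!r}")
        if iv.end - iv.start > chrom_sizes[iv.chrom]:
            raise ValueError(f"interval longer than chromosome {iv.chrom}")
    rng = np.random.default_rng(seed)
    avoid = list(masked_bp) if masked_bp is not None else []
    out = []
    # longest first improves packing feasibility; output order is irrelevant
    order = sorted(template, key=lambda iv: iv.start - iv.end)
    max_restarts = 50  # sequential placement can fragment; restart the replicate
    for _ in range(n_replicates):
        placed: list[Interval] = []
        for restart in range(max_restarts + 1):
            placed = []
            complete = True
            for iv in order:
                size = chrom_sizes[iv.chrom]
                length = iv.end - iv.start
                for attempt in range(max_retries):
                    s = int(rng.integers(0, size - length + 1))
                    cand = Interval(iv.chrom, s, s + length, iv.strand, iv.name)
                    clash = any(
                        o.chrom == cand.chrom and o.start < cand.end and cand.start < o.end
                        for o in placed + avoid
                    )
                    if not clash:
                        placed.append(cand)
                        break
                else:
                    complete = False
                    break
            if complete:
                break
            if restart == max_restarts:
                raise ValueError(
                    f"could not place the template intervals without overlap "
                    f"after {max_retries} retries x {max_restarts} restarts"
                )
        out.append(RegionSet(placed))
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact enumeration when ``len(x)*len(y) <= 400`` and there are no ties
    across the pooled sample; otherwise normal approximation with tie and
    continuity correction.  p is clamped away from 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires two nonempty samples")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # every observation tied: the test is degenerate, no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= EXACT_PRODUCT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), max(float(res.pvalue), _MIN_P)


def enrichment_test(
    m: ContactMatrix,
    regions: RegionSet,
    focal: RegionSet | None = None,
    chrom_sizes: dict[str, int] | None = None,
    n_replicates: int = 10,
    seed: int = 0,
) -> EnrichmentResult:
    """Observed contact values vs. per-replicate random-region nulls.

    One Mann-Whitney U test per replicate (observed list vs. that
    replicate's null list); ``p_mean`` is the arithmetic mean of the
    replicate p-values.  The direction compares the observed mean with the
    mean of null means.
    """
    if chrom_sizes is None:
        chrom_sizes = {m.chrom: m.start_bp + m.n_bins * m.bin_size}
    if focal is None:
        observed = contacts_within(m, regions)
    else:
        observed = contacts_between(m, focal, regions)
    nulls = sample_random_regions(regions, chrom_sizes, n_replicates, seed)
    null_values, u_stats, p_values = [], [], []
    for null_set in nulls:
        if focal is None:
            nv = contacts_within(m, null_set)
        else:
            nv = contacts_between(m, focal, null_set)
        u, p = mann_whitney_u(observed, nv)
        null_values.append(nv)
        u_stats.append(u)
        p_values.append(p)
    null_means = np.array([nv.mean() for nv in null_values])
    obs_mean = float(observed.mean())
    if obs_mean > null_means.mean():
        direction = "enriched"
    elif obs_mean < null_means.mean():
        direction = "depleted"
    else:
        direction = "none"
    return EnrichmentResult(
        observed_values=observed,
        null_values=null_values,
        u_stats=np.array(u_stats),
        p_values=np.array(p_values),
        p_mean=float(np.mean(p_values)),
        n_replicates=n_replicates,
        seed=seed,
        direction=direction,
        observed_mean=obs_mean,
        null_means=null_means,
    )


def _cross_pairs(
    m: ContactMatrix, set_x: RegionSet, set_y: RegionSet
) -> np.ndarray:
    xi = np.nonzero(_in_set_bins(m, set_x))[0]
    yi = np.nonzero(_in_set_bins(m, set_y))[0]
    if xi.size == 0 or yi.size == 0:
        raise ValueError("empty bin set")
    vals = m.values[np.ix_(xi, yi)]
    off_diag = xi[:, None] != yi[None, :]
    vals = vals[off_diag & np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined pairs between the two sets")
    return vals


def pcc_difference(
    pcc_a: ContactMatrix, pcc_b: ContactMatrix, set_x: RegionSet, set_y: RegionSet
) -> float:
    """Mean correlation over (x, y) bin pairs in condition a minus b."""
    if pcc_a.n_bins != pcc_b.n_bins or pcc_a.bin_size != pcc_b.bin_size:
        raise ValueError("correlation matrices are on different frames")
    return float(_cross_pairs(pcc_a, set_x, set_y).mean() -
                 _cross_pairs(pcc_b, set_x, set_y).mean())


def contacts_log2fc(
    m_a: ContactMatrix,
    m_b: ContactMatrix,
    set_x: RegionSet,
    gene_sets: dict[str, RegionSet],
) -> pd.DataFrame:
    """log2 of mean contacts (condition a over b) between ``set_x`` and each
    gene set.  Matrices should be depth-matched first (see
    :func:`hicarch.matrix.downsample_counts`)."""
    rows = []
    for name, gs in gene_sets.items():
        mean_a = _cross_pairs(m_a, set_x, gs).mean()
        mean_b = _cross_pairs(m_b, set_x, gs).mean()
        fc = np.log2(mean_a / mean_b) if mean_a > 0 and mean_b > 0 else np.nan
        rows.append({"gene_set": name, "mean_a": mean_a, "mean_b": mean_b,
                     "log2fc": fc})
    return pd.DataFrame(rows).set_index("gene_set")
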