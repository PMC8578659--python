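"""Entropy-based stage-specificity scoring and staging clusters.

A gene's specificity across K stages is one minus the normalized Shannon
entropy of its stage profile; genes above a threshold are clustered with
K-means on row-standardized log2(TPM+1) profiles and the clusters relabeled
C1..Ck by the stage at which their centroid peaks.  A per-cluster shift test
compares treatment-induced log2 expression shifts of a cluster with the
all-gene shift distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from hicarch.enrichment import mann_whitney_u

__all__ = [
    "ExpressionMatrix",
    "StageClusters",
    "specificity_score",
    "cluster_stage_genes",
    "cluster_shift_test",
]

DEFAULT_THRESHOLD = 0.2
DEFAULT_K = 4
KMEANS_RESTARTS = 50


@dataclass
class ExpressionMatrix:
    """Genes x stages abundance table (TPM unless ``log_transformed``)."""

    data: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self):
        self.data = self.data.astype(float)
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 stages")
        if not self.log_transformed and (self.data.values < 0).any():
            raise ValueError("TPM values must be nonnegative")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def stages(self) -> pd.Index:
        return self.data.columns


@dataclass
class StageClusters:
    scores: pd.Series
    threshold: float
    assignments: pd.Series  # gene -> "C1".."Ck", passing genes only
    k: int
    centroids: pd.DataFrame  # cluster label x stage (standardized profile)

    def genes_in(self, label: str) -> pd.Index:
        return self.assignments.index[self.assignments == label]


def specificity_score(e: ExpressionMatrix, on_log: bool = False) -> pd.Series:
    """Per-gene specificity 1 - H(p)/log2(K) in [0, 1].

    ``p`` is the gene's stage profile normalized to sum 1 (of raw TPM by
    default, of log2(TPM+1) with ``on_log``); H is Shannon entropy in bits
    with 0*log(0) = 0.  Genes with an all-zero profile are NaN.
    """
    x = e.data.values
    if on_log and not e.log_transformed:
        x = np.log2(x + 1.0)
    k = x.shape[1]
    if k < 2:
        raise ValueError("specificity needs at least 2 stages")
    totals = x.sum(axis=1)
    scores = np.full(x.shape[0], np.nan)
    ok = totals > 0
    p = x[ok] / totals[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    h = -plogp.sum(axis=1)
    scores[ok] = 1.0 - h / np.log2(k)
    return pd.Series(scores, index=e.genes, name="specificity")


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def cluster_stage_genes(
    e: ExpressionMatrix,
    scores: pd.Series | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> StageClusters:
    """K-means staging clusters of stage-specific genes.

    Genes with specificity above ``threshold`` are clustered on their
    row-standardized log2(TPM+1) profiles (k-means++, ``KMEANS_RESTARTS``
    restarts, best inertia kept).  Clusters are renamed C1..Ck in order of
    the stage at which their centroid peaks, earliest first.
    """
    if scores is None:
        scores = specificity_score(e)
    passing = scores.index[scores > threshold]
    if len(passing) < k:
        raise ValueError(
            f"only {len(passing)} genes pass the threshold; need at least k={k}"
        )
    logx = e.data.loc[passing].values
    if not e.log_transformed:
        logx = np.log2(logx + 1.0)
    z = _standardize_rows(logx)
    km = KMeans(n_clusters=k, init="k-means++", n_init=KMEANS_RESTARTS,
                random_state=seed)
    raw_labels = km.fit_predict(z)
    # stable relabeling: order clusters by centroid peak stage, earliest first
    peaks = km.cluster_centers_.argmax(axis=1)
    order = np.lexsort((np.arange(k), peaks))
    rename = {int(orig): f"C{rank + 1}" for rank, orig in enumerate(order)}
    labels = pd.Series([rename[int(l)] for l in raw_labels], index=passing,
                       name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=[f"C{i + 1}" for i in range(k)],
        columns=e.stages,
    )
    return StageClusters(scores=scores, threshold=threshold, assignments=labels,
                         k=k, centroids=centroids)


def cluster_shift_test(
    clusters: StageClusters,
    expr_control: pd.Series,
    expr_treated: pd.Series,
) -> pd.DataFrame:
    """Per-cluster treatment shift vs. the all-gene shift distribution.

    The shift of a gene is log2(TPM_treated + 1) - log2(TPM_control + 1);
    each cluster's shifts are compared with the shifts of all genes by a
    two-sided Mann-Whitney U test.  Empty clusters give a NaN row.
    """
    common = expr_control.index.intersection(expr_treated.index)
    shifts = (np.log2(expr_treated.loc[common] + 1.0)
              - np.log2(expr_control.loc[common] + 1.0))
    rows = []
    for label in [f"C{i + 1}" for i in range(clusters.k)]:
        genes = clusters.genes_in(label).intersection(common)
        if len(genes) == 0:
            rows.append({"cluster": label, "n_genes": 0, "mean_shift": np.nan,
                         "median_shift": np.nan, "U": np.nan, "p": np.nan})
            continue
        cs = shifts.loc[genes].values
        u, p = mann_whitney_u(cs, shifts.values)
        rows.append({
            "cluster": label,
            "n_genes": len(genes),
            "mean_shift": float(cs.mean()),
            "median_shift": float(np.median(cs)),
            "U": u,
            "p": p,
        })
    return pd.DataFrame(rows).set_index("cluster")
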