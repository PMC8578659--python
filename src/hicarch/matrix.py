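"""Contact-matrix data model and core transforms.

A :class:`ContactMatrix` holds a single-chromosome (cis) square symmetric
matrix at a fixed bin size, together with a per-bin exclusion mask.  Four
kinds are distinguished: ``raw`` counts, ``balanced`` (doubly stochastic up
to scale), ``oe`` (observed over distance-expected) and ``pcc`` (row-wise
Pearson correlation).  Undefined entries in transformed kinds are NaN.

The transforms implemented here are:

* :func:`downsample_counts` — multivariate-hypergeometric downsampling of the
  read-pair multiset, for depth-matching conditions before comparison.
* :func:`kr_balance` — matrix balancing to equal row sums on unmasked bins.
* :func:`observed_expected` — division by the per-diagonal mean.
* :func:`pearson_correlation_matrix` — row-vector Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactMatrix",
    "GenomeTrack",
    "BalanceError",
    "downsample_counts",
    "kr_balance",
    "observed_expected",
    "pearson_correlation_matrix",
]

_SYM_TOL = 1e-9

VALID_KINDS = ("raw", "balanced", "oe", "pcc")


class BalanceError(RuntimeError):
    """Raised when matrix balancing cannot reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class ContactMatrix:
    """Square symmetric cis contact matrix on a fixed genomic frame.

    Parameters
    ----------
    chrom:
        Chromosome name (passed through verbatim).
    bin_size:
        Bases per bin.
    values:
        ``(n, n)`` symmetric array.  Nonnegative integers for ``kind='raw'``;
        reals (NaN = undefined) for transformed kinds.
    kind:
        One of ``raw``, ``balanced``, ``oe``, ``pcc``.
    start_bp:
        Genomic start of bin 0 (0-based).  Bin ``b`` covers
        ``[start_bp + b*bin_size, start_bp + (b+1)*bin_size)``.
    mask:
        Per-bin boolean, True = excluded (e.g. zero coverage).
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    kind: str = "raw"
    start_bp: int = 0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        d = self.values - self.values.T
        if np.nanmax(np.abs(d), initial=0.0) > _SYM_TOL:
            raise ValueError("contact matrix must be symmetric within 1e-9")
        if self.kind == "raw":
            v = self.values
            finite = v[np.isfinite(v)]
            if finite.size and (finite < 0).any():
                raise ValueError("raw counts must be nonnegative")
            if finite.size and np.max(np.abs(finite - np.round(finite))) > 1e-6:
                raise ValueError("raw counts must be integers")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise ValueError("mask length must equal bin count")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, pos_bp: int) -> int:
        """Bin index containing a genomic position (may be out of range)."""
        return (int(pos_bp) - self.start_bp) // self.bin_size

    def bin_start(self, b: int) -> int:
        return self.start_bp + b * self.bin_size

    def upper_triangle_total(self) -> float:
        """Sum of counts over i <= j (each unordered pair counted once)."""
        iu = np.triu_indices(self.n_bins)
        return float(np.nansum(self.values[iu]))

    def with_values(self, values: np.ndarray, kind: str, mask=None) -> "ContactMatrix":
        return ContactMatrix(
            chrom=self.chrom,
            bin_size=self.bin_size,
            values=values,
            kind=kind,
            start_bp=self.start_bp,
            mask=self.mask.copy() if mask is None else np.asarray(mask, bool),
        )

    def copy(self) -> "ContactMatrix":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass
class GenomeTrack:
    """One real value per bin on the same frame as a :class:`ContactMatrix`."""

    chrom: str
    bin_size: int
    values: np.ndarray
    start_bp: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def same_frame(self, other) -> bool:
        return (
            self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and self.start_bp == other.start_bp
            and self.n_bins == other.n_bins
        )


def zero_marginal_mask(m: ContactMatrix) -> np.ndarray:
    """Mask bins whose row sum of raw counts is zero (union with existing mask)."""
    marg = np.nansum(m.values, axis=0)
    return m.mask | (marg <= 0)


def downsample_counts(m: ContactMatrix, target_total: int, seed: int) -> ContactMatrix:
    """Subsample read pairs without replacement to an exact total.

    The upper triangle (i <= j) is treated as a multiset of pairs; a
    multivariate-hypergeometric draw retains exactly ``target_total`` of them,
    and symmetry is restored by mirroring.
    """
    if m.kind != "raw":
        raise ValueError("downsampling requires a raw count matrix")
    target_total = int(target_total)
    iu = np.triu_indices(m.n_bins)
    counts = np.round(m.values[iu]).astype(np.int64)
    total = int(counts.sum())
    if target_total > total:
        raise ValueError(
            f"insufficient depth: requested {target_total} pairs, only {total} available"
        )
    if target_total == total:
        return m.copy()
    rng = np.random.default_rng(seed)
    kept = rng.multivariate_hypergeometric(counts, target_total, method="marginals")
    out = np.zeros_like(m.values)
    out[iu] = kept
    out = out + out.T - np.diag(np.diag(out))
    return m.with_values(out, kind="raw")


def _sinkhorn_symmetric(a: np.ndarray, tol: float, max_iter: int):
    """Symmetric diagonal scaling of ``a`` to unit row sums.

    Iterates ``w <- w / sqrt(rowsum(D_w a D_w))`` which converges to the
    unique doubly stochastic scaling for symmetric matrices with support.
    Returns (balanced matrix, weights, achieved row-sum CV).
    """
    n = a.shape[0]
    w = np.ones(n)
    cv = np.inf
    for _ in range(max_iter):
        s = w * (a @ w)  # row sums of D_w a D_w
        if not np.all(s > 0):
            raise BalanceError("zero row sum encountered during balancing")
        cv = float(np.std(s) / np.mean(s))
        if cv < tol:
            break
        w = w / np.sqrt(s)
    b = (w[:, None] * a) * w[None, :]
    rs = b.sum(axis=1)
    b /= rs.mean()
    w = w / np.sqrt(rs.mean())
    return b, w, cv


def kr_balance(
    m: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000
) -> tuple[ContactMatrix, np.ndarray]:
    """Balance a raw matrix so unmasked row sums are all equal to 1.

    Bins with zero marginal are masked first.  Returns the balanced matrix
    (masked rows/columns NaN) and the per-bin balancing weights ``w`` such
    that ``balanced = w_i * raw_ij * w_j`` (NaN at masked bins).

    Raises
    ------
    BalanceError
        If every bin is masked, or the row-sum coefficient of variation is
        still above ``tol`` after ``max_iter`` iterations.
    """
    if m.kind != "raw":
        raise ValueError("kr_balance expects a raw count matrix")
    mask = zero_marginal_mask(m)
    keep = ~mask
    if keep.sum() == 0:
        raise BalanceError("matrix has no nonzero bins")
    sub = m.values[np.ix_(keep, keep)]
    bal, w_sub, cv = _sinkhorn_symmetric(sub, tol, max_iter)
    if cv >= tol:
        raise BalanceError(
            f"balancing did not converge after {max_iter} iterations "
            f"(row-sum CV {cv:.3e} > tol {tol:.3e})",
            residual=cv,
        )
    n = m.n_bins
    out = np.full((n, n), np.nan)
    out[np.ix_(keep, keep)] = bal
    weights = np.full(n, np.nan)
    weights[keep] = w_sub
    return m.with_values(out, kind="balanced", mask=mask), weights


def observed_expected(m: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean of unmasked entries at its distance.

    Expected value at genomic distance ``d`` bins is the arithmetic mean of
    defined entries on diagonal ``d``.  Diagonals with no defined entries, or
    zero mean, are NaN in the output.  The per-diagonal mean of the result is
    1 over defined entries by construction.
    """
    if m.kind not in ("balanced", "raw"):
        raise ValueError("observed_expected expects a balanced (or raw) matrix")
    n = m.n_bins
    keep = ~m.mask
    out = np.full((n, n), np.nan)
    v = m.values
    for d in range(n):
        diag = np.diagonal(v, offset=d)
        ok = keep[: n - d] & keep[d:] & np.isfinite(diag)
        if not ok.any():
            continue
        exp = diag[ok].mean()
        if exp <= 0:
            continue
        idx = np.nonzero(ok)[0]
        out[idx, idx + d] = diag[idx] / exp
        out[idx + d, idx] = out[idx, idx + d]
    return m.with_values(out, kind="oe")


def pearson_correlation_matrix(m: ContactMatrix) -> ContactMatrix:
    """Pearson correlation between row vectors of an O/E matrix.

    Correlations use mutually defined positions only.  Zero-variance rows
    are NaN.  Diagonal entries are 1 for unmasked, defined bins.
    """
    if m.kind != "oe":
        raise ValueError("pearson_correlation_matrix expects an O/E matrix")
    n = m.n_bins
    keep = ~m.mask
    out = np.full((n, n), np.nan)
    sub = m.values[np.ix_(keep, keep)]
    if sub.size == 0:
        return m.with_values(out, kind="pcc")
    if np.isfinite(sub).all():
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(sub)
    else:
        ma = np.ma.masked_invalid(sub)
        c = np.ma.corrcoef(ma, allow_masked=True).filled(np.nan)
    c = np.asarray(c, dtype=float)
    # zero-variance rows come out NaN from corrcoef already; clip fp overshoot
    c = np.clip(c, -1.0, 1.0)
    out[np.ix_(keep, keep)] = c
    out = (out + out.T) / 2.0
    return m.with_values(out, kind="pcc")
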