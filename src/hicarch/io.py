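"""Plain-text readers and writers.

Formats: whitespace triplet contact text ("bin_i bin_j count", upper
triangle sufficient, ``# key=value`` header lines carry the frame), dense
TSV matrices, bedGraph tracks, BED3/BED6 region sets, BEDPE anchor pairs
and genes x stages expression TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hicarch.aggregates import LoopAnchors
from hicarch.matrix import ContactMatrix, GenomeTrack
from hicarch.regions import Interval, RegionSet


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""


# ---------------------------------------------------------------- matrices

def _parse_header(lines) -> dict:
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            break
        for token in line[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    return meta


def read_triplet_matrix(
    path,
    chrom: str | None = None,
    bin_size: int | None = None,
    n_bins: int | None = None,
    start_bp: int = 0,
    kind: str = "raw",
) -> ContactMatrix:
    """Read "bin_i bin_j value" text; header lines may provide the frame."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()
    meta = _parse_header(lines)
    chrom = chrom or meta.get("chrom")
    bin_size = bin_size or (int(meta["bin_size"]) if "bin_size" in meta else None)
    n_bins = n_bins or (int(meta["n_bins"]) if "n_bins" in meta else None)
    start_bp = int(meta.get("start_bp", start_bp))
    kind = meta.get("kind", kind)
    if chrom is None or bin_size is None:
        raise FormatError(f"{path}: chrom and bin_size required (header or arguments)")
    rows, cols, vals = [], [], []
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        try:
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if i < 0 or j < 0:
            raise FormatError(f"{path}:{lineno}: negative bin index")
        rows.append(i)
        cols.append(j)
        vals.append(v)
    if n_bins is None:
        if not rows:
            raise FormatError(f"{path}: empty matrix and no n_bins given")
        n_bins = max(max(rows), max(cols)) + 1
    m = np.zeros((n_bins, n_bins))
    for i, j, v in zip(rows, cols, vals):
        if i >= n_bins or j >= n_bins:
            raise FormatError(f"{path}: bin index out of range for n_bins={n_bins}")
        m[i, j] = v
        m[j, i] = v
    return ContactMatrix(chrom, bin_size, m, kind=kind, start_bp=start_bp)


def write_triplet_matrix(m: ContactMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# chrom={m.chrom} bin_size={m.bin_size} n_bins={m.n_bins} "
            f"start_bp={m.start_bp} kind={m.kind}\n"
        )
        iu = np.triu_indices(m.n_bins)
        for i, j in zip(*iu):
            v = m.values[i, j]
            if np.isfinite(v) and v != 0:
                if m.kind == "raw":
                    fh.write(f"{i} {j} {int(round(v))}\n")
                else:
                    fh.write(f"{i} {j} {v:.10g}\n")


def read_dense_matrix(
    path, chrom: str | None = None, bin_size: int | None = None,
    start_bp: int = 0, kind: str = "raw",
) -> ContactMatrix:
    """Dense TSV with a header row of bin start coordinates."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()
    meta = _parse_header(lines)
    chrom = chrom or meta.get("chrom")
    bin_size = bin_size or (int(meta["bin_size"]) if "bin_size" in meta else None)
    start_bp = int(meta.get("start_bp", start_bp))
    kind = meta.get("kind", kind)
    body = [l for l in lines if l.strip() and not l.startswith("#")]
    if not body:
        raise FormatError(f"{path}: no data rows")
    header = body[0].rstrip("\n").split("\t")
    starts = [int(x) for x in header]
    if bin_size is None:
        if len(starts) > 1:
            bin_size = starts[1] - starts[0]
        else:
            raise FormatError(f"{path}: cannot infer bin_size from one column")
    values = np.array(
        [[float(x) for x in l.rstrip("\n").split("\t")] for l in body[1:]]
    )
    if chrom is None:
        raise FormatError(f"{path}: chrom required (header or argument)")
    return ContactMatrix(chrom, bin_size, values, kind=kind,
                         start_bp=start_bp or starts[0])


def write_dense_matrix(m: ContactMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# chrom={m.chrom} bin_size={m.bin_size} start_bp={m.start_bp} "
            f"kind={m.kind}\n"
        )
        fh.write("\t".join(str(m.bin_start(b)) for b in range(m.n_bins)) + "\n")
        for row in m.values:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


# ------------------------------------------------------------------ tracks

def read_bedgraph(path, chrom: str, bin_size: int, n_bins: int,
                  start_bp: int = 0) -> GenomeTrack:
    """Read a bedGraph onto a fixed bin frame (NaN where uncovered)."""
    path = Path(path)
    values = np.full(n_bins, np.nan)
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if c != chrom:
                continue
            lo = max(s - start_bp, 0) // bin_size
            hi = -(-(min(e - start_bp, n_bins * bin_size)) // bin_size)
            values[lo:hi] = v
    return GenomeTrack(chrom, bin_size, values, start_bp=start_bp)


def write_bedgraph(track: GenomeTrack, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for b, v in enumerate(track.values):
            if np.isfinite(v):
                s = track.start_bp + b * track.bin_size
                fh.write(f"{track.chrom}\t{s}\t{s + track.bin_size}\t{v:.10g}\n")


# ----------------------------------------------------------------- regions

def read_regions(path) -> RegionSet:
    """Read BED3/BED6 (tab-separated, 0-based half-open), sorted stably."""
    path = Path(path)
    intervals = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            intervals.append(Interval(chrom, start, end, strand, name))
    return RegionSet(intervals).sort()


def write_regions(regions: RegionSet, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_loops(path) -> dict[str, LoopAnchors]:
    """Read BEDPE (chrom1 start1 end1 chrom2 start2 end2), cis rows only,
    grouped per chromosome."""
    path = Path(path)
    per_chrom: dict[str, list] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 fields")
            c1, s1, e1, c2, s2, e2 = (
                parts[0], int(parts[1]), int(parts[2]),
                parts[3], int(parts[4]), int(parts[5]),
            )
            if c1 != c2:
                raise FormatError(f"{path}:{lineno}: trans loop not supported")
            per_chrom.setdefault(c1, []).append(((s1, e1), (s2, e2)))
    return {c: LoopAnchors.from_intervals(c, pairs) for c, pairs in per_chrom.items()}


def intersect_regions(a: RegionSet, b: RegionSet, c: RegionSet) -> RegionSet:
    """Intervals of ``a`` overlapping >= 1 bp of some interval in both ``b``
    and ``c`` (the three-set intersection used to define hub regions)."""

    def _index(rs: RegionSet):
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in rs.chroms():
            ivs = sorted(rs.on_chrom(chrom), key=lambda iv: iv.start)
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.maximum.accumulate(np.array([iv.end for iv in ivs], np.int64))
            by_chrom[chrom] = (starts, ends)
        return by_chrom

    def _hits(idx, iv) -> bool:
        if iv.chrom not in idx:
            return False
        starts, cummax_end = idx[iv.chrom]
        k = int(np.searchsorted(starts, iv.end, side="left"))
        return k > 0 and cummax_end[k - 1] > iv.start

    ib, ic = _index(b), _index(c)
    return RegionSet([iv for iv in a if _hits(ib, iv) and _hits(ic, iv)])


# -------------------------------------------------------------- expression

def read_expression(path) -> pd.DataFrame:
    """Genes x stages TSV, first column = gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 stage columns")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# -------------------------------------------------------------------- json

def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default,
                                     allow_nan=True) + "\n")
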