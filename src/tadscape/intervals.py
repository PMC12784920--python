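"""Genomic interval arithmetic on 0-based half-open intervals.

All functions operate on pandas DataFrames carrying at least the columns
``chrom`` (str), ``start`` (int) and ``end`` (int).  Intervals are 0-based
half-open, the convention of BED.  These primitives (merge, bp-Jaccard,
nearest-midpoint offsets) are the atoms of the boundary-comparison stages
and are deliberately written from first principles so that they can be
checked exactly against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def as_intervals(records) -> pd.DataFrame:
    """Build an interval frame from an iterable of (chrom, start, end) tuples."""
    df = pd.DataFrame(records, columns=BED_COLS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def total_bp(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals whose gap is <= ``gap`` bp (overlapping/adjacent at gap=0).

    Returns a sorted, non-redundant frame with columns chrom/start/end.
    Idempotent for any fixed gap.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    if len(df) == 0:
        return pd.DataFrame(columns=BED_COLS).astype({"start": np.int64, "end": np.int64})
    df = sort_intervals(df[BED_COLS])
    out = []
    for chrom, g in df.groupby("chrom", sort=True):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        cummax_end = np.maximum.accumulate(ends)
        # a new run starts where the interval lies more than `gap` past everything before it
        new_run = np.concatenate([[True], starts[1:] > cummax_end[:-1] + gap])
        run_id = np.cumsum(new_run) - 1
        for rid in range(run_id[-1] + 1):
            sel = run_id == rid
            out.append((chrom, int(starts[sel].min()), int(ends[sel].max())))
    return as_intervals(out)


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Disjoint intersection intervals of two interval sets (each merged first)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    out = []
    for chrom in sorted(set(ma["chrom"]) & set(mb["chrom"])):
        ga = ma[ma["chrom"] == chrom]
        gb = mb[mb["chrom"] == chrom]
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if lo < hi:
                out.append((chrom, int(lo), int(hi)))
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return as_intervals(out)


@dataclass(frozen=True)
class JaccardResult:
    """Base-pair Jaccard statistics between two interval sets."""

    jaccard: float
    intersect_bp: int
    union_bp: int
    n_intersections: int
    degenerate: bool = False  # both inputs empty; J defined as 1 by convention


def jaccard_stats(a: pd.DataFrame, b: pd.DataFrame) -> JaccardResult:
    """Intersection-over-union in base pairs, plus the intersection-interval count.

    Symmetric in its arguments.  Two empty sets have zero union; J is then
    defined as 1 and flagged degenerate rather than returned as NaN.
    """
    inter = intersect_intervals(a, b)
    union = merge_intervals(pd.concat([a[BED_COLS], b[BED_COLS]], ignore_index=True))
    ibp, ubp = total_bp(inter), total_bp(union)
    if ubp == 0:
        return JaccardResult(1.0, 0, 0, 0, degenerate=True)
    return JaccardResult(ibp / ubp, ibp, ubp, len(inter))


def midpoints(df: pd.DataFrame) -> np.ndarray:
    return (df["start"].to_numpy() + df["end"].to_numpy()) / 2.0


def nearest_midpoint_offsets(a: pd.DataFrame, b: pd.DataFrame):
    """Distance from each interval midpoint in ``a`` to the nearest midpoint in ``b``.

    Matching is per chromosome; equidistant neighbours resolve to the
    smaller-coordinate one.  Intervals of ``a`` on chromosomes absent from
    ``b`` are excluded and counted.

    Returns
    -------
    offsets : DataFrame with chrom, midpoint_a, midpoint_b, offset_bp
    n_excluded : int
    """
    a = sort_intervals(a)
    b = sort_intervals(b)
    rows = []
    n_excluded = 0
    b_by_chrom = {c: np.sort(midpoints(g)) for c, g in b.groupby("chrom")}
    for chrom, g in a.groupby("chrom"):
        mids_a = midpoints(g)
        if chrom not in b_by_chrom or len(b_by_chrom[chrom]) == 0:
            n_excluded += len(g)
            continue
        mids_b = b_by_chrom[chrom]
        idx = np.searchsorted(mids_b, mids_a)
        for m, k in zip(mids_a, idx):
            cands = []
            if k > 0:
                cands.append(mids_b[k - 1])
            if k < len(mids_b):
                cands.append(mids_b[k])
            # smaller coordinate first, so ties pick it (strict < when comparing)
            best = cands[0]
            for c in cands[1:]:
                if abs(c - m) < abs(best - m):
                    best = c
            rows.append((chrom, float(m), float(best), float(abs(best - m))))
    offsets = pd.DataFrame(rows, columns=["chrom", "midpoint_a", "midpoint_b", "offset_bp"])
    return offsets, n_excluded


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two intervals on one chromosome; 0 if they overlap/touch."""
    return max(start_b - end_a, start_a - end_b, 0)


def min_gap_to_set(df: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Smallest gap from [start, end) to any interval of ``df`` on ``chrom`` (inf if none)."""
    g = df[df["chrom"] == chrom]
    if len(g) == 0:
        return float("inf")
    s = g["start"].to_numpy()
    e = g["end"].to_numpy()
    gaps = np.maximum(np.maximum(s - end, start - e), 0)
    return float(gaps.min())


# ---------------------------------------------------------------------------
# plain-text serialization (BED / bedGraph)

def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file; extra columns become name/score when present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + [f"col{i}" for i in range(len(names), df.shape[1])]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path, cols=None) -> None:
    cols = cols or [c for c in ["chrom", "start", "end", "name", "score"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(path, chrom: str, bin_size: int, values: np.ndarray) -> None:
    """Write a per-bin track as bedGraph; NaN bins are skipped."""
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df
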