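"""TAD and boundary calling from balanced contact matrices.

The caller follows the multi-scale insulation approach: for every bin and a
ladder of window sizes, the mean contact in the "diamond" spanning the bin
(rows upstream x columns downstream) is computed, z-scored per window size
across the chromosome, and averaged across windows into a per-bin
TAD-separation score.  Boundaries are local minima of that score whose
local contrast (delta) clears a threshold and whose diamond contacts are
significantly depleted relative to flanking within-domain diamonds
(one-sided rank-sum, Benjamini-Hochberg controlled).

Boundary strength (BS) is the delta at the called minimum: the mean of the
separation score over flanking bins minus the score at the boundary, so
larger BS = stronger insulation.  Note this is a package-defined scale
(z-score units); external insulation tools report deltas on their own
scales, so BS values are comparable within a run, not across tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .matrix import ContactMatrix

DEFAULT_MIN_DEPTH_BP = 250
DEFAULT_MAX_DEPTH_BP = 2_000_000
DEFAULT_STEP_BP = 25_000
DEFAULT_DELTA_SPAN_BINS = 10


@dataclass
class InsulationTrack:
    """Multi-scale insulation scores for one chromosome.

    ``raw``/``z`` are (n_windows, n_bins) diamond-mean matrices (NaN where a
    window does not fit or covers no unmasked pair); ``tad_sep`` is the mean
    z across windows and ``delta`` its local-contrast track.
    """

    chrom: str
    bin_size: int
    windows_bins: np.ndarray
    raw: np.ndarray
    z: np.ndarray
    tad_sep: np.ndarray
    delta: np.ndarray
    matrix: ContactMatrix  # retained for the boundary significance test


def _diamond_means(counts: np.ndarray, mask: np.ndarray, w: int) -> np.ndarray:
    """Mean contact in the w-bin diamond at every bin, NaN where undefined.

    The diamond at bin i is the rectangle rows [i-w, i) x cols [i+1, i+w+1),
    restricted to unmasked rows/columns.  Computed with 2-D prefix sums.
    """
    n = counts.shape[0]
    out = np.full(n, np.nan)
    if 2 * w >= n:
        return out
    Cm = np.where(np.outer(mask, mask), counts, 0.0)
    P = np.zeros((n + 1, n + 1))
    P[1:, 1:] = Cm.cumsum(0).cumsum(1)
    V = np.zeros(n + 1)
    V[1:] = np.cumsum(mask.astype(np.int64))
    i = np.arange(w, n - w)
    r0, r1 = i - w, i            # rows [i-w, i)
    c0, c1 = i + 1, i + w + 1    # cols [i+1, i+w+1)
    sums = P[r1, c1] - P[r1, c0] - P[r0, c1] + P[r0, c0]
    cnt = (V[r1] - V[r0]) * (V[c1] - V[c0])
    with np.errstate(invalid="ignore"):
        out[i] = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return out


def window_sizes_bins(bin_size: int, min_depth_bp: int = DEFAULT_MIN_DEPTH_BP,
                      max_depth_bp: int = DEFAULT_MAX_DEPTH_BP,
                      step_bp: int = DEFAULT_STEP_BP) -> np.ndarray:
    """Unique diamond window sizes in bins for a depth ladder given in bp.

    Each depth maps to ``max(1, round(depth / bin_size))`` bins, so sub-bin
    depths collapse to the 1-bin minimum window.
    """
    if min_depth_bp >= max_depth_bp:
        raise ValueError("min_depth_bp must be < max_depth_bp")
    depths = np.append(np.arange(min_depth_bp, max_depth_bp + 1, step_bp),
                       max_depth_bp)
    return np.unique(np.maximum(1, np.round(depths / bin_size).astype(int)))


def insulation_scores(m: ContactMatrix, min_depth_bp: int = DEFAULT_MIN_DEPTH_BP,
                      max_depth_bp: int = DEFAULT_MAX_DEPTH_BP,
                      step_bp: int = DEFAULT_STEP_BP,
                      delta_span_bins: int = DEFAULT_DELTA_SPAN_BINS) -> InsulationTrack:
    """Compute the multi-scale insulation / TAD-separation track.

    Windows that do not fit on the chromosome are skipped with a warning.
    Z-scoring is per window size across the chromosome's defined bins.
    """
    if not m.balanced:
        warnings.warn(f"{m.chrom}: scoring an unbalanced matrix")
    n = m.n_bins
    windows = window_sizes_bins(m.bin_size, min_depth_bp, max_depth_bp, step_bp)
    fits = windows < (n + 1) // 2
    if not fits.all():
        warnings.warn(f"{m.chrom}: skipping {int((~fits).sum())} window size(s) "
                      f"exceeding the chromosome")
        windows = windows[fits]
    if len(windows) == 0:
        raise ValueError(f"{m.chrom}: no usable window size")
    raw = np.vstack([_diamond_means(m.counts, m.mask, int(w)) for w in windows])
    z = np.full_like(raw, np.nan)
    for k in range(raw.shape[0]):
        row = raw[k]
        ok = np.isfinite(row)
        if ok.sum() >= 2 and np.nanstd(row) > 0:
            z[k, ok] = (row[ok] - row[ok].mean()) / row[ok].std()
        elif ok.any():
            z[k, ok] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        tad_sep = np.nanmean(z, axis=0)

    d = delta_span_bins
    delta = np.full(n, np.nan)
    for i in range(n):
        if not np.isfinite(tad_sep[i]):
            continue
        left = tad_sep[max(0, i - d): i]
        right = tad_sep[i + 1: i + 1 + d]
        sides = [s[np.isfinite(s)] for s in (left, right)]
        sides = [s for s in sides if len(s)]
        if sides:
            delta[i] = float(np.mean([s.mean() for s in sides])) - tad_sep[i]
    return InsulationTrack(chrom=m.chrom, bin_size=m.bin_size, windows_bins=windows,
                           raw=raw, z=z, tad_sep=tad_sep, delta=delta, matrix=m)


def _diamond_values(counts, mask, i: int, w: int) -> np.ndarray:
    lo, hi = i - w, i + w + 1
    if lo < 0 or hi > counts.shape[0]:
        return np.empty(0)
    block = counts[lo:i, i + 1:hi]
    sel = np.outer(mask[lo:i], mask[i + 1:hi])
    return block[sel]


def call_boundaries(track: InsulationTrack, delta_min: float = 0.1,
                    fdr_alpha: float = 0.05, test_window_bins: int = 5,
                    min_separation_bins: int = 3,
                    sample: str = "", group: str = "") -> pd.DataFrame:
    """Call boundary bins from a TAD-separation track.

    Candidates are strict local minima (ties broken leftmost) with local
    contrast ``delta >= delta_min``; candidates closer than
    ``min_separation_bins`` suppress each other, keeping the deeper minimum
    (masked bins can split one insulation trough into a double dip, so
    without suppression a single boundary would be called twice).  Each
    surviving candidate's diamond contacts are compared against the two
    flanking within-domain diamonds by a one-sided Wilcoxon rank-sum test;
    BH-adjusted q-values <= ``fdr_alpha`` are kept.  ``test_window_bins``
    should stay below about half the typical domain size so the flanking
    diamonds remain within-domain.

    Returns a frame with chrom, start, end (the single boundary bin),
    bin, strength (BS = delta at the minimum), p_value, q_value, sample, group.
    """
    ts = track.tad_sep
    n = len(ts)
    if n == 0 or not np.isfinite(ts).any():
        raise ValueError("empty insulation track")
    cand = []
    for i in range(1, n - 1):
        if not (np.isfinite(ts[i - 1]) and np.isfinite(ts[i]) and np.isfinite(ts[i + 1])):
            continue
        if ts[i] < ts[i - 1] and ts[i] <= ts[i + 1]:
            d = track.delta[i]
            if np.isfinite(d) and d >= delta_min:
                cand.append(i)
    # non-minimum suppression: deepest trough wins within min_separation_bins
    kept_pos: list[int] = []
    for i in sorted(cand, key=lambda i: ts[i]):
        if all(abs(i - j) > min_separation_bins for j in kept_pos):
            kept_pos.append(i)
    cand = sorted(kept_pos)
    if not cand:
        return _boundary_frame([], track, sample, group)

    counts, mask = track.matrix.counts, track.matrix.mask
    pvals = []
    for k, i in enumerate(cand):
        # shrink the window so flanking diamonds stay clear of neighbouring
        # candidate boundaries (else the "within-domain" reference is itself
        # depleted and the contrast vanishes)
        gap_l = i - cand[k - 1] if k > 0 else i
        gap_r = cand[k + 1] - i if k + 1 < len(cand) else n - 1 - i
        w = min(test_window_bins, i, n - 1 - i, max(1, min(gap_l, gap_r) // 2))
        b = _diamond_values(counts, mask, i, w) if w >= 1 else np.empty(0)
        flank = np.concatenate([
            _diamond_values(counts, mask, i - w, w),
            _diamond_values(counts, mask, i + w, w),
        ]) if w >= 1 else np.empty(0)
        if len(b) == 0 or len(flank) == 0:
            pvals.append(1.0)
            continue
        res = _sps.mannwhitneyu(b, flank, alternative="less")
        pvals.append(float(res.pvalue))
    _, qvals, _, _ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
    kept = [(i, p, q) for i, p, q in zip(cand, pvals, qvals) if q <= fdr_alpha]
    return _boundary_frame(kept, track, sample, group)


def _boundary_frame(rows, track: InsulationTrack, sample: str, group: str) -> pd.DataFrame:
    recs = []
    for i, p, q in rows:
        recs.append({
            "chrom": track.chrom,
            "start": i * track.bin_size,
            "end": (i + 1) * track.bin_size,
            "bin": i,
            "strength": float(track.delta[i]),
            "p_value": p,
            "q_value": q,
            "sample": sample,
            "group": group,
        })
    cols = ["chrom", "start", "end", "bin", "strength", "p_value", "q_value",
            "sample", "group"]
    return pd.DataFrame(recs, columns=cols)


def segment_tads(boundaries: pd.DataFrame, chrom: str, chrom_length: int) -> pd.DataFrame:
    """Partition a chromosome into TADs at boundary positions.

    Boundary interval starts act as breakpoints; the chromosome ends close
    the first and last domain.  Zero boundaries yield one whole-chromosome
    domain.
    """
    b = boundaries[boundaries["chrom"] == chrom] if len(boundaries) else boundaries
    pts = sorted(set(int(s) for s in (b["start"] if len(b) else [])
                     if 0 < s < chrom_length))
    edges = [0] + pts + [chrom_length]
    recs = [{"chrom": chrom, "start": a, "end": b_, "size_bp": b_ - a}
            for a, b_ in zip(edges[:-1], edges[1:]) if b_ > a]
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "size_bp"])


def tad_summary(sample: str, bin_size: int, segments: pd.DataFrame,
                boundaries: pd.DataFrame) -> dict:
    """Per-sample domain summary row: count, median / IQR size, median BS."""
    sizes_mb = segments["size_bp"].to_numpy() / 1e6
    q1, med, q3 = (np.percentile(sizes_mb, [25, 50, 75]) if len(sizes_mb)
                   else (np.nan, np.nan, np.nan))
    return {
        "Sample": sample,
        "Resolution_bp": bin_size,
        "TAD_count": int(len(segments)),
        "Median_size_Mb": float(med),
        "IQR_lo_Mb": float(q1),
        "IQR_hi_Mb": float(q3),
        "Median_BS": float(boundaries["strength"].median()) if len(boundaries) else np.nan,
    }
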