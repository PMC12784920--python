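"""Group-wise comparison of TAD-boundary landscapes (case vs control).

Per-sample boundary calls are harmonized (±1-bin merge), combined into
lenient/stringent group consensus sets, and contrasted between groups by
base-pair Jaccard overlap, nearest-boundary offsets, gain/loss
classification under a positional tolerance, and a per-boundary test of the
boundary-strength difference ΔBS = BS_case − BS_control with
Benjamini-Hochberg FDR control.

With one BS value per animal per boundary the study's random-intercept model
collapses to a two-sample comparison, so the per-boundary test here is
Welch's t on replicate BS values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from . import intervals as iv

CTRL = "CTRL"
UNDER = "UNDER"


@dataclass
class BoundarySetCollection:
    """Per-sample boundary calls plus group labels and (optionally) BS tracks.

    ``per_sample`` maps sample -> boundary frame (chrom/start/end/strength...).
    ``tracks`` maps sample -> {chrom -> per-bin delta (BS) array}; required
    only for :func:`delta_bs_test`.
    """

    per_sample: Dict[str, pd.DataFrame]
    group_of: Dict[str, str]
    bin_size: int
    tracks: Optional[Dict[str, Dict[str, np.ndarray]]] = None

    def samples(self, group: str):
        out = [s for s, g in self.group_of.items() if g == group]
        if not out:
            raise ValueError(f"unknown or empty group {group!r}")
        return out


def harmonize(calls: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """Merge one sample's boundary intervals within ±1 bin into a non-redundant set."""
    if len(calls) and "bin_size" in calls.columns and calls["bin_size"].nunique() > 1:
        raise ValueError("mixed bin sizes in one boundary set")
    return iv.merge_intervals(calls[iv.BED_COLS] if len(calls) else calls, gap=bin_size)


def consensus(coll: BoundarySetCollection, group: str,
              stringency: str = "lenient") -> pd.DataFrame:
    """Group consensus boundaries.

    lenient: merged union over replicates (present in >= 1 replicate);
    stringent: lenient intervals supported by every replicate within ±1 bin.
    """
    samples = coll.samples(group)
    harm = {s: harmonize(coll.per_sample[s], coll.bin_size) for s in samples}
    lenient = iv.merge_intervals(pd.concat([harm[s] for s in samples], ignore_index=True),
                                 gap=coll.bin_size)
    if stringency == "lenient":
        return lenient
    if stringency != "stringent":
        raise ValueError(f"unknown stringency {stringency!r}")
    keep = []
    for row in lenient.itertuples(index=False):
        if all(iv.min_gap_to_set(harm[s], row.chrom, row.start, row.end) <= coll.bin_size
               for s in samples):
            keep.append(row)
    return iv.as_intervals([(r.chrom, r.start, r.end) for r in keep])


def nearest_offsets(a: pd.DataFrame, b: pd.DataFrame, bin_size: int):
    """Nearest-midpoint offsets of set a against set b plus alignment summary."""
    offsets, n_excluded = iv.nearest_midpoint_offsets(a, b)
    off = offsets["offset_bp"].to_numpy()
    summary = {
        "offset_median_bp": float(np.median(off)) if len(off) else np.nan,
        "offset_mean_bp": float(np.mean(off)) if len(off) else np.nan,
        "frac_within_1bin": float(np.mean(off <= bin_size)) if len(off) else np.nan,
        "frac_within_2bin": float(np.mean(off <= 2 * bin_size)) if len(off) else np.nan,
        "n_offsets": int(len(off)),
        "n_excluded_no_chrom": int(n_excluded),
    }
    return offsets, summary


def classify_specific(coll: BoundarySetCollection, tolerance_bp: int = 40_000):
    """Classify boundaries as CTRL-specific, case-specific or conserved.

    A case-specific boundary is a lenient-consensus case interval with no
    control boundary (from any replicate) within ``tolerance_bp``; control-
    specific conversely.  Conserved intervals are union-set intervals with
    support from both groups within ±1 bin.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    len_c = consensus(coll, CTRL, "lenient")
    len_u = consensus(coll, UNDER, "lenient")
    raw_c = pd.concat([harmonize(coll.per_sample[s], coll.bin_size)
                       for s in coll.samples(CTRL)], ignore_index=True)
    raw_u = pd.concat([harmonize(coll.per_sample[s], coll.bin_size)
                       for s in coll.samples(UNDER)], ignore_index=True)

    def _specific(own: pd.DataFrame, other_raw: pd.DataFrame) -> pd.DataFrame:
        keep = [r for r in own.itertuples(index=False)
                if iv.min_gap_to_set(other_raw, r.chrom, r.start, r.end) > tolerance_bp]
        return iv.as_intervals([(r.chrom, r.start, r.end) for r in keep])

    under_specific = _specific(len_u, raw_c)
    ctrl_specific = _specific(len_c, raw_u)
    union = iv.merge_intervals(pd.concat([len_c, len_u], ignore_index=True),
                               gap=coll.bin_size)
    conserved = iv.as_intervals([
        (r.chrom, r.start, r.end) for r in union.itertuples(index=False)
        if iv.min_gap_to_set(raw_c, r.chrom, r.start, r.end) <= coll.bin_size
        and iv.min_gap_to_set(raw_u, r.chrom, r.start, r.end) <= coll.bin_size
    ])
    return ctrl_specific, under_specific, conserved


def _greedy_pairs(mids_c: np.ndarray, mids_u: np.ndarray, window: float):
    """Pair midpoints by ascending distance, each used at most once.

    Ties in distance resolve to the smaller control coordinate.
    """
    cand = []
    j0 = np.searchsorted(mids_u, mids_c - window, side="left")
    j1 = np.searchsorted(mids_u, mids_c + window, side="right")
    for i, (a, b) in enumerate(zip(j0, j1)):
        for j in range(a, b):
            cand.append((abs(mids_u[j] - mids_c[i]), mids_c[i], i, j))
    cand.sort()
    used_c, used_u, pairs = set(), set(), []
    for _, _, i, j in cand:
        if i not in used_c and j not in used_u:
            used_c.add(i)
            used_u.add(j)
            pairs.append((i, j))
    return sorted(pairs)


def delta_bs_test(coll: BoundarySetCollection, pairing_window_bp: int = 50_000,
                  fdr_alpha: float = 0.10, universe: str = "group"):
    """Pair boundaries between groups and test per-boundary ΔBS.

    Boundaries are paired by nearest midpoints within ``pairing_window_bp``
    (greedy by ascending distance, each boundary used once); unpaired
    boundaries are excluded from testing but remain available to the
    gain/loss tallies.  Replicate BS values are read from each sample's
    delta track at the bin of that group's paired boundary midpoint;
    ΔBS = mean over case replicates − mean over control replicates, and each
    paired locus gets a Welch's t test across replicates, BH-adjusted.

    ``universe`` selects the boundary sets fed to pairing: "group" uses the
    group-merged lenient consensus; "replicate" uses the pooled per-replicate
    harmonized boundaries (a larger universe in which near-coincident
    replicate calls pair individually).

    Returns (pairs frame, summary dict).
    """
    if coll.tracks is None:
        raise ValueError("delta_bs_test requires per-sample BS tracks")
    for group in (CTRL, UNDER):
        if len(coll.samples(group)) < 1:
            raise ValueError(f"need >= 1 replicate in group {group}")
    if universe == "group":
        set_c = consensus(coll, CTRL, "lenient")
        set_u = consensus(coll, UNDER, "lenient")
    elif universe == "replicate":
        set_c = iv.sort_intervals(pd.concat(
            [harmonize(coll.per_sample[s], coll.bin_size) for s in coll.samples(CTRL)],
            ignore_index=True))
        set_u = iv.sort_intervals(pd.concat(
            [harmonize(coll.per_sample[s], coll.bin_size) for s in coll.samples(UNDER)],
            ignore_index=True))
    else:
        raise ValueError(f"unknown universe {universe!r}")

    bs = coll.bin_size
    recs = []
    for chrom in sorted(set(set_c["chrom"]) | set(set_u["chrom"])):
        gc = set_c[set_c["chrom"] == chrom].reset_index(drop=True)
        gu = set_u[set_u["chrom"] == chrom].reset_index(drop=True)
        mc, mu = iv.midpoints(gc), iv.midpoints(gu)
        for i, j in _greedy_pairs(mc, mu, pairing_window_bp):
            bin_c, bin_u = int(mc[i] // bs), int(mu[j] // bs)
            vals_c = _track_values(coll, CTRL, chrom, bin_c)
            vals_u = _track_values(coll, UNDER, chrom, bin_u)
            if len(vals_c) == 0 or len(vals_u) == 0:
                continue
            dbs = float(np.mean(vals_u) - np.mean(vals_c))
            p = _welch_p(vals_u, vals_c)
            recs.append({
                "chrom": chrom,
                "ctrl_start": int(gc.loc[i, "start"]), "ctrl_end": int(gc.loc[i, "end"]),
                "under_start": int(gu.loc[j, "start"]), "under_end": int(gu.loc[j, "end"]),
                "offset_bp": float(abs(mu[j] - mc[i])),
                "bs_ctrl": float(np.mean(vals_c)), "bs_under": float(np.mean(vals_u)),
                "delta_bs": dbs, "p_value": p,
            })
    pairs = pd.DataFrame(recs)
    if len(pairs):
        _, q, _, _ = multipletests(pairs["p_value"].to_numpy(), alpha=fdr_alpha,
                                   method="fdr_bh")
        pairs["q_value"] = q
    else:
        pairs["q_value"] = pd.Series(dtype=float)
    d = pairs["delta_bs"].to_numpy() if len(pairs) else np.empty(0)
    summary = {
        "n_paired": int(len(pairs)),
        "delta_bs_median": float(np.median(d)) if len(d) else np.nan,
        "delta_bs_iqr": (tuple(np.percentile(d, [25, 75])) if len(d) else (np.nan, np.nan)),
        "median_abs_delta_bs": float(np.median(np.abs(d))) if len(d) else np.nan,
        "n_significant": int((pairs["q_value"] < fdr_alpha).sum()) if len(pairs) else 0,
        "fdr_alpha": fdr_alpha,
    }
    return pairs, summary


def _track_values(coll: BoundarySetCollection, group: str, chrom: str, b: int) -> np.ndarray:
    vals = []
    for s in coll.samples(group):
        tr = coll.tracks.get(s, {}).get(chrom)
        if tr is not None and 0 <= b < len(tr) and np.isfinite(tr[b]):
            vals.append(float(tr[b]))
    return np.asarray(vals)


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or len(y) < 2:
        return 1.0
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    p = _sps.ttest_ind(x, y, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def compare_groups(coll: BoundarySetCollection, tolerance_bp: int = 40_000,
                   pairing_window_bp: int = 50_000, fdr_alpha: float = 0.10) -> dict:
    """Full between-group comparison summary (Jaccard, offsets, specificity, ΔBS)."""
    len_c = consensus(coll, CTRL, "lenient")
    len_u = consensus(coll, UNDER, "lenient")
    jac = iv.jaccard_stats(len_c, len_u)
    _, off = nearest_offsets(len_c, len_u, coll.bin_size)
    ctrl_sp, under_sp, conserved = classify_specific(coll, tolerance_bp)
    out = {
        "jaccard": jac.jaccard,
        "intersect_bp": jac.intersect_bp,
        "union_bp": jac.union_bp,
        "n_intersections": jac.n_intersections,
        "jaccard_ge_0.50": bool(jac.jaccard >= 0.50),
        "n_ctrl_specific": int(len(ctrl_sp)),
        "n_under_specific": int(len(under_sp)),
        "n_conserved": int(len(conserved)),
        **off,
    }
    if coll.tracks is not None:
        _, dbs = delta_bs_test(coll, pairing_window_bp, fdr_alpha)
        out.update({f"dbs_{k}" if not k.startswith(("n_", "delta", "median", "fdr"))
                    else k: v for k, v in dbs.items()})
    return out
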