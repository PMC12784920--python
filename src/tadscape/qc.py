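"""Valid-pair QC summaries for Hi-C libraries.

Consumes per-sample pair-count tables (valid pairs partitioned into cis and
trans, optionally with short-range-cis and duplicate counts as reported by
HiC-Pro) and computes the per-sample cis ratios and cohort-level summaries
used to judge library quality before any matrix-level analysis.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd


class QCValidationError(ValueError):
    """A pair-count row violates a conservation invariant."""


@dataclass(frozen=True)
class PairStats:
    """Valid-pair counts for one Hi-C library.

    ``valid_pairs`` must equal ``cis + trans``; ``cis_short`` (short-range cis
    pairs) and ``duplicates`` are optional because many published tables omit
    them.
    """

    sample: str
    valid_pairs: int
    cis: int
    trans: int
    group: Optional[str] = None
    cis_short: Optional[int] = None
    duplicates: Optional[int] = None

    def validate(self) -> None:
        if min(self.valid_pairs, self.cis, self.trans) < 0:
            raise QCValidationError(f"{self.sample}: negative count")
        if self.cis + self.trans != self.valid_pairs:
            raise QCValidationError(
                f"{self.sample}: cis ({self.cis}) + trans ({self.trans}) != "
                f"valid_pairs ({self.valid_pairs})"
            )
        if self.cis_short is not None and self.cis_short > self.cis:
            raise QCValidationError(f"{self.sample}: cis_short exceeds cis")


def cis_ratio(stats: PairStats) -> float:
    """Percentage of valid pairs that are cis (full precision; round at display)."""
    if stats.valid_pairs == 0:
        raise QCValidationError(f"{stats.sample}: cis ratio undefined for 0 valid pairs")
    return 100.0 * stats.cis / stats.valid_pairs


@dataclass(frozen=True)
class QCSummary:
    per_sample_cis_ratio_pct: dict
    mean_cis_ratio_pct: float
    min_cis_ratio_pct: float
    max_cis_ratio_pct: float
    median_valid_pairs: float
    range_valid_pairs: tuple
    mean_short_range_pct_of_cis: Optional[float] = None
    mean_duplicate_pct: Optional[float] = None


def summarize_qc(rows: Sequence[PairStats]) -> QCSummary:
    """Cohort QC summary.

    The mean cis ratio is the unweighted mean of per-sample ratios (matching
    how such tables report an "average" ratio); the median of valid-pair
    counts uses the standard even-n midpoint.  Optional short-range/duplicate
    summaries are computed only when every row carries the field.
    """
    if len(rows) == 0:
        raise ValueError("summarize_qc needs at least one row")
    for r in rows:
        r.validate()
    ratios = {r.sample: cis_ratio(r) for r in rows}
    vals = [r.valid_pairs for r in rows]
    short = None
    if all(r.cis_short is not None for r in rows):
        short = statistics.fmean(100.0 * r.cis_short / r.cis for r in rows if r.cis > 0)
    dup = None
    if all(r.duplicates is not None for r in rows):
        dup = statistics.fmean(100.0 * r.duplicates / r.valid_pairs for r in rows)
    return QCSummary(
        per_sample_cis_ratio_pct=ratios,
        mean_cis_ratio_pct=statistics.fmean(ratios.values()),
        min_cis_ratio_pct=min(ratios.values()),
        max_cis_ratio_pct=max(ratios.values()),
        median_valid_pairs=statistics.median(vals),
        range_valid_pairs=(min(vals), max(vals)),
        mean_short_range_pct_of_cis=short,
        mean_duplicate_pct=dup,
    )


# ---------------------------------------------------------------------------
# TSV I/O (header dialect: Sample  Valid_Pairs  Cis  Trans  [Cis_Ratio_pct] [Group])

_REQUIRED = ["Sample", "Valid_Pairs", "Cis", "Trans"]


def read_pair_stats(path) -> list[PairStats]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"pair-stats table missing columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            PairStats(
                sample=str(r["Sample"]),
                valid_pairs=int(r["Valid_Pairs"]),
                cis=int(r["Cis"]),
                trans=int(r["Trans"]),
                group=str(r["Group"]) if "Group" in df.columns else None,
                cis_short=int(r["Cis_Short"]) if "Cis_Short" in df.columns else None,
                duplicates=int(r["Duplicates"]) if "Duplicates" in df.columns else None,
            )
        )
    return rows


def write_pair_stats(rows: Sequence[PairStats], path) -> None:
    recs = []
    for r in rows:
        rec = {
            "Sample": r.sample,
            "Valid_Pairs": r.valid_pairs,
            "Cis": r.cis,
            "Trans": r.trans,
            "Cis_Ratio_pct": round(cis_ratio(r), 2),
        }
        if r.group is not None:
            rec["Group"] = r.group
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def format_qc_report(summary: QCSummary) -> str:
    """Human-readable QC report (ratios rounded half-even to 2 decimals)."""
    lines = ["Hi-C valid-pair QC summary", "=" * 30]
    for s, v in summary.per_sample_cis_ratio_pct.items():
        lines.append(f"  {s}: cis ratio {v:.2f}%")
    lines += [
        f"mean cis ratio:   {summary.mean_cis_ratio_pct:.2f}%",
        f"cis ratio range:  {summary.min_cis_ratio_pct:.2f}%-{summary.max_cis_ratio_pct:.2f}%",
        f"median valid pairs: {summary.median_valid_pairs / 1e6:.1f} million",
        f"valid-pair range: {summary.range_valid_pairs[0] / 1e6:.1f}-"
        f"{summary.range_valid_pairs[1] / 1e6:.1f} million",
    ]
    if summary.mean_short_range_pct_of_cis is not None:
        lines.append(f"mean short-range share of cis: {summary.mean_short_range_pct_of_cis:.1f}%")
    if summary.mean_duplicate_pct is not None:
        lines.append(f"mean duplicate rate: {summary.mean_duplicate_pct:.2f}%")
    return "\n".join(lines) + "\n"
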