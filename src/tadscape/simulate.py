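"""Synthetic Hi-C study generator with known ground truth.

Emulates the data of a two-group (case vs control), two-replicate Hi-C
comparison: block-TAD contact matrices with power-law distance decay on a
TAD scaffold shared between groups, where the case group ("UNDER") differs
only by a small number of planted extra boundaries that subdivide existing
control domains.  Alongside the matrices it generates Table-style pair-count
tables, gene models, and the truth set (boundary positions and expected
density-hotspot windows) needed for parameter-recovery tests.

The contact model: E[c_ij] ∝ max(|i−j|, 0.5)^(−α) · (1 + β·[i,j in the same
TAD of the group's segmentation]), scaled so the expected total count of the
full symmetric matrix equals ``depth``; counts are Poisson draws (or
gamma-Poisson when ``replicate_noise`` > 0, adding between-replicate
overdispersion).  All randomness derives from a single master seed through
named, stable substreams, so every artefact is reproducible bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hotspots import GeneModel, write_genes_gff3
from .matrix import ContactMatrix, write_hicpro
from .qc import PairStats, write_pair_stats
from . import intervals as iv

GROUPS = ("CTRL", "UNDER")

# planted gains must keep this many bins clear of scaffold boundaries so that
# a gain called ±1 bin off stays > the 40 kb specificity tolerance away from
# any control boundary (also called ±1 bin off)
GAIN_CLEARANCE_BINS = 4


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of a synthetic two-group Hi-C study.

    ``tad_median_bp``/``tad_log_sd`` parameterize the lognormal TAD-size
    sampler (target median ~0.70 Mb); ``decay_exponent`` is the power-law
    distance-decay exponent α; ``intra_tad_boost`` the within-domain contact
    enrichment β; ``depth`` the expected total contacts per chromosome
    matrix.  ``planted_gains`` are bin-aligned (chrom, position-bp)
    boundaries present only in the UNDER group, each strictly inside a CTRL
    TAD.  ``bin_bias_sd`` is the lognormal sigma of a per-bin multiplicative
    coverage bias shared by every sample (emulating mappability and
    restriction-site density variation, the visibility bias ICE removes);
    a ``bad_bin_frac`` fraction of bins additionally get near-zero
    visibility, mimicking the unmappable bins that coverage filtering masks.
    """

    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000})
    bin_size: int = 40_000
    tad_median_bp: int = 700_000
    tad_log_sd: float = 0.35
    decay_exponent: float = 1.0
    intra_tad_boost: float = 3.0
    depth: float = 2_000_000.0
    n_replicates_per_group: int = 2
    planted_gains: Tuple[Tuple[str, int], ...] = ()
    replicate_noise: float = 0.0
    bin_bias_sd: float = 0.15
    bad_bin_frac: float = 0.03
    cis_fraction: float = 0.55
    pair_depth: float = 5_000_000.0
    seed: int = 0

    def validate(self) -> None:
        if self.bin_size <= 0 or self.depth <= 0 or self.decay_exponent <= 0:
            raise ValueError("bin_size, depth and decay_exponent must be positive")
        if self.intra_tad_boost < 0 or self.replicate_noise < 0:
            raise ValueError("intra_tad_boost and replicate_noise must be >= 0")
        for chrom, length in self.chrom_sizes.items():
            if length < 2 * self.bin_size:
                raise ValueError(f"{chrom}: chromosome shorter than 2 bins")
        for chrom, pos in self.planted_gains:
            if chrom not in self.chrom_sizes:
                raise ValueError(f"planted gain on unknown chromosome {chrom}")
            if pos % self.bin_size != 0:
                raise ValueError(f"planted gain at {pos} is not bin-aligned")

    def n_bins(self, chrom: str) -> int:
        return int(np.ceil(self.chrom_sizes[chrom] / self.bin_size))

    def samples(self) -> List[Tuple[str, str, int]]:
        """(sample_name, group, replicate) triples of the design."""
        out = []
        for group in GROUPS:
            for r in range(self.n_replicates_per_group):
                out.append((f"{group}_{r + 1}", group, r))
        return out


def _rng(design: SyntheticDesign, *labels) -> np.random.Generator:
    """Deterministic substream from the master seed and a label path."""
    words = [design.seed & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            words.append(zlib.crc32(lab.encode()) & 0x7FFFFFFF)
        else:
            words.append(int(lab) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# TAD scaffold and segmentations

def scaffold_boundaries(design: SyntheticDesign, chrom: str) -> np.ndarray:
    """Shared (CTRL) TAD boundary bins for one chromosome.

    TAD sizes are lognormal with the configured median; boundaries within
    ``GAIN_CLEARANCE_BINS`` of a planted gain are removed so that each gain
    falls strictly inside a control domain.
    """
    rng = _rng(design, "scaffold", chrom)
    n = design.n_bins(chrom)
    med_bins = design.tad_median_bp / design.bin_size
    bounds = []
    pos = 0
    while True:
        size = int(np.clip(np.round(rng.lognormal(np.log(med_bins), design.tad_log_sd)),
                           5, 4 * med_bins))
        pos += size
        if pos >= n - 3:
            break
        bounds.append(pos)
    bounds = np.array(bounds, dtype=int)
    gains = gain_bins(design).get(chrom, np.empty(0, dtype=int))
    if len(gains):
        far = np.all(np.abs(bounds[:, None] - gains[None, :]) > GAIN_CLEARANCE_BINS, axis=1)
        bounds = bounds[far]
    return bounds


def gain_bins(design: SyntheticDesign) -> Dict[str, np.ndarray]:
    out: Dict[str, List[int]] = {}
    for chrom, pos in design.planted_gains:
        out.setdefault(chrom, []).append(pos // design.bin_size)
    return {c: np.array(sorted(v), dtype=int) for c, v in out.items()}


def group_boundaries(design: SyntheticDesign, group: str, chrom: str) -> np.ndarray:
    """Boundary bins of a group's segmentation (scaffold [+ planted gains])."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    base = scaffold_boundaries(design, chrom)
    if group == "UNDER":
        extra = gain_bins(design).get(chrom, np.empty(0, dtype=int))
        return np.unique(np.concatenate([base, extra]))
    return base


# ---------------------------------------------------------------------------
# contact matrices

def bin_bias(design: SyntheticDesign, chrom: str) -> np.ndarray:
    """Per-bin multiplicative visibility bias (shared across samples and groups)."""
    n = design.n_bins(chrom)
    if design.bin_bias_sd == 0 and design.bad_bin_frac == 0:
        return np.ones(n)
    rng = _rng(design, "bias", chrom)
    b = rng.lognormal(0.0, design.bin_bias_sd, size=n)
    bad = rng.random(n) < design.bad_bin_frac
    b[bad] *= rng.uniform(0.05, 0.2, size=int(bad.sum()))
    return b


def expected_matrix(design: SyntheticDesign, group: str, chrom: str,
                    include_bias: bool = True) -> np.ndarray:
    """Analytic expectation E[c_ij] for one chromosome matrix (full, symmetric)."""
    design.validate()
    n = design.n_bins(chrom)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    deff = np.maximum(d, 0.5)
    base = deff ** (-design.decay_exponent)
    bounds = group_boundaries(design, group, chrom)
    # adjacent domains share the boundary bin (two contact triangles touching
    # at the boundary locus), so the boundary bin's crossing diamond is the
    # unique unboosted one and the insulation trough has a single minimum
    dom_hi = np.searchsorted(bounds, idx, side="right")
    dom_lo = dom_hi - np.isin(idx, bounds).astype(int)
    same = (np.maximum(dom_lo[:, None], dom_lo[None, :])
            <= np.minimum(dom_hi[:, None], dom_hi[None, :]))
    e = base * (1.0 + design.intra_tad_boost * same)
    if include_bias:
        b = bin_bias(design, chrom)
        e = e * np.outer(b, b)
    return e * (design.depth / e.sum())


def simulate_contact_matrix(design: SyntheticDesign, group: str, replicate: int,
                            chrom: str) -> ContactMatrix:
    """Draw one replicate's contact matrix for one chromosome.

    Deterministic under (seed, group, replicate, chrom).
    """
    e = expected_matrix(design, group, chrom)
    rng = _rng(design, "matrix", group, replicate, chrom)
    lam = e.copy()
    if design.replicate_noise > 0:
        shape = 1.0 / design.replicate_noise
        lam *= rng.gamma(shape, 1.0 / shape, size=lam.shape)
    iu = np.triu_indices(lam.shape[0])
    draws = rng.poisson(np.triu(lam))
    m = np.zeros_like(lam)
    m[iu] = draws[iu]
    m = m + np.triu(m, 1).T
    return ContactMatrix(chrom=chrom, bin_size=design.bin_size, counts=m)


def simulate_sample(design: SyntheticDesign, group: str,
                    replicate: int) -> Dict[str, ContactMatrix]:
    return {chrom: simulate_contact_matrix(design, group, replicate, chrom)
            for chrom in design.chrom_sizes}


# ---------------------------------------------------------------------------
# pair statistics and genes

def simulate_pair_stats(design: SyntheticDesign) -> List[PairStats]:
    """Per-sample valid/cis/trans counts with cis + trans = valid by construction."""
    design.validate()
    rows = []
    for sample, group, rep in design.samples():
        rng = _rng(design, "pairs", group, rep)
        valid = int(rng.poisson(design.pair_depth))
        cis = int(rng.binomial(valid, design.cis_fraction)) if valid else 0
        rows.append(PairStats(sample=sample, group=group, valid_pairs=valid,
                              cis=cis, trans=valid - cis))
    return rows


def simulate_genes(design: SyntheticDesign, genes_per_mb: float = 2.5) -> List[GeneModel]:
    """Random strand-aware gene models; every planted hotspot window gets >= 1 gene."""
    design.validate()
    rng = _rng(design, "genes")
    genes: List[GeneModel] = []
    k = 0
    for chrom in sorted(design.chrom_sizes):
        length = design.chrom_sizes[chrom]
        n_genes = int(genes_per_mb * length / 1e6)
        starts = np.sort(rng.integers(0, length - 60_000, size=n_genes))
        for s in starts:
            glen = int(np.clip(rng.lognormal(np.log(25_000), 0.6), 2_000, 300_000))
            end = min(int(s) + glen, length)
            k += 1
            genes.append(GeneModel(gene_id=f"gene{k:04d}", chrom=chrom,
                                   start=int(s), end=end,
                                   strand="+" if rng.random() < 0.5 else "-"))
    for _, row in truth_hotspot_windows(design).iterrows():
        covered = any(g.chrom == row.Chr and g.start < row.End and g.end > row.Start
                      for g in genes)
        if not covered:
            k += 1
            genes.append(GeneModel(gene_id=f"gene{k:04d}", chrom=row.Chr,
                                   start=int(row.Start) + 100_000,
                                   end=int(row.Start) + 150_000, strand="+"))
    return genes


# ---------------------------------------------------------------------------
# truth set

@dataclass(frozen=True)
class TruthSet:
    """Ground truth of a synthetic study, for parameter-recovery checks."""

    boundaries_ctrl: Dict[str, np.ndarray]   # boundary positions in bp
    boundaries_under: Dict[str, np.ndarray]
    hotspot_windows: pd.DataFrame            # tiles expected to satisfy Δ >= 2
    genes: List[GeneModel]

    def boundary_intervals(self, group: str, bin_size: int) -> pd.DataFrame:
        src = self.boundaries_under if group == "UNDER" else self.boundaries_ctrl
        recs = [(c, int(p), int(p) + bin_size) for c, ps in src.items() for p in ps]
        return iv.as_intervals(recs)


def truth_hotspot_windows(design: SyntheticDesign,
                          window_bp: int = 1_000_000, delta_min: int = 2) -> pd.DataFrame:
    """1 Mb tiles whose planted-gain count reaches the hotspot threshold.

    Because groups share the scaffold, the expected window Δ equals the
    number of planted gains whose midpoint falls in the tile.
    """
    rows = []
    gb = gain_bins(design)
    for chrom in sorted(design.chrom_sizes):
        length = design.chrom_sizes[chrom]
        gains = gb.get(chrom, np.empty(0, dtype=int))
        mids = gains * design.bin_size + design.bin_size / 2
        n_win = int(np.ceil(length / window_bp))
        counts = np.bincount(np.minimum((mids // window_bp).astype(int), n_win - 1),
                             minlength=n_win) if len(mids) else np.zeros(n_win, int)
        for kwin in np.flatnonzero(counts >= delta_min):
            rows.append({"Chr": chrom, "Start": int(kwin) * window_bp,
                         "End": min((int(kwin) + 1) * window_bp, length),
                         "Delta": int(counts[kwin])})
    return pd.DataFrame(rows, columns=["Chr", "Start", "End", "Delta"])


def truth_set(design: SyntheticDesign) -> TruthSet:
    design.validate()
    ctrl = {c: scaffold_boundaries(design, c) * design.bin_size
            for c in design.chrom_sizes}
    under = {c: group_boundaries(design, "UNDER", c) * design.bin_size
             for c in design.chrom_sizes}
    return TruthSet(boundaries_ctrl=ctrl, boundaries_under=under,
                    hotspot_windows=truth_hotspot_windows(design),
                    genes=simulate_genes(design))


def make_design(seed: int = 0, planted: bool = True, **overrides) -> SyntheticDesign:
    """Default study design: 2 x 20 Mb chromosomes at 40 kb, 2 vs 2 replicates.

    With ``planted=True``, six UNDER-specific boundaries are planted: three in
    one chr1 megabase tile (an expected Δ=+3 hotspot), two in one chr2 tile
    (Δ=+2), and one isolated gain on chr1 (below the hotspot threshold, so
    hotspot specificity is exercised).  Gains sit well inside tiles and clear
    of scaffold boundaries by construction.
    """
    if "planted_gains" not in overrides and planted and "chrom_sizes" not in overrides:
        overrides["planted_gains"] = (
            ("chr1", 12_240_000), ("chr1", 12_480_000), ("chr1", 12_720_000),
            ("chr2", 5_280_000), ("chr2", 5_600_000),
            ("chr1", 17_360_000),
        )
    design = SyntheticDesign(seed=seed, **overrides)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# on-disk study

def write_study(design: SyntheticDesign, outdir) -> Path:
    """Write a complete synthetic study: HiC-Pro matrices, pair stats, genes, truth.

    Layout: ``matrices/<sample>.<chrom>.matrix/.bed``, ``pair_stats.tsv``,
    ``samples.tsv``, ``genes.gff3``, ``truth/`` (boundary BEDs and hotspot
    windows TSV), ``chrom_sizes.tsv``.
    """
    out = Path(outdir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for sample, group, rep in design.samples():
        for chrom in design.chrom_sizes:
            m = simulate_contact_matrix(design, group, rep, chrom)
            write_hicpro(m, out / "matrices" / f"{sample}.{chrom}.matrix",
                         out / "matrices" / f"{sample}.{chrom}.bed",
                         chrom_length=design.chrom_sizes[chrom])
    pd.DataFrame([{"Sample": s, "Group": g} for s, g, _ in design.samples()]).to_csv(
        out / "samples.tsv", sep="\t", index=False)
    write_pair_stats(simulate_pair_stats(design), out / "pair_stats.tsv")
    truth = truth_set(design)
    write_genes_gff3(truth.genes, out / "genes.gff3")
    for group in GROUPS:
        iv.write_bed(truth.boundary_intervals(group, design.bin_size),
                     out / "truth" / f"boundaries_{group}.bed")
    truth.hotspot_windows.to_csv(out / "truth" / "hotspot_windows.tsv",
                                 sep="\t", index=False)
    pd.DataFrame(sorted(design.chrom_sizes.items()),
                 columns=["chrom", "length"]).to_csv(
        out / "chrom_sizes.tsv", sep="\t", index=False, header=False)
    return out
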