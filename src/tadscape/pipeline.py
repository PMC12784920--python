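"""End-to-end pipeline: QC -> balance -> call -> compare -> hotspots -> annotate.

The pipeline consumes a study directory (as produced by
:func:`tadscape.simulate.write_study`, or assembled by hand from HiC-Pro
exports) and writes every intermediate and final table under an output
directory, together with a run manifest (config snapshot, input checksums,
stage summaries).  Two entry modes are supported: from contact matrices
(boundaries are called internally) or from precomputed per-sample boundary
BED + strength bedGraph files (the calling stage is skipped).

All analysis stages are deterministic; randomness lives only in the
synthetic-data generator.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import hotspots as hs
from . import intervals as iv
from . import qc as qcmod
from .insulation import call_boundaries, insulation_scores, segment_tads, tad_summary
from .matrix import ice_balance, read_hicpro, replicate_correlation
from .simulate import make_design, write_study

log = logging.getLogger("tadscape")


@dataclass
class PipelineConfig:
    """All pipeline parameters; the defaults are the study's stated values
    (40 kb bins, ±1-bin merge, ±50 kb ΔBS pairing, ±40 kb specificity and
    de-dup tolerances, 1 Mb windows, Δ >= 2 hotspots, ΔBS FDR 0.10,
    TSS ± 2 kb promoters, ±1 Mb nearest-TSS, <= 250 kb tier 3)."""

    input_dir: str = "."
    output_dir: str = "results"
    bin_size: int = 40_000
    min_depth_bp: int = 250
    max_depth_bp: int = 2_000_000
    step_bp: int = 25_000
    delta_min: float = 0.1
    call_fdr: float = 0.05
    fdr_alpha: float = 0.10
    merge_bins: int = 1
    pairing_window_bp: int = 50_000
    specificity_tol_bp: int = 40_000
    dedupe_bp: int = 40_000
    window_bp: int = 1_000_000
    hotspot_delta_min: int = 2
    promoter_pad: int = 2_000
    tss_max: int = 1_000_000
    tier3_max: int = 250_000
    concordance_min: float = 0.80
    seed: int = 0

    def validate(self) -> None:
        for name in ("pairing_window_bp", "specificity_tol_bp", "dedupe_bp",
                     "promoter_pad", "tss_max", "tier3_max", "merge_bins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bin_size <= 0 or self.window_bp <= 0:
            raise ValueError("bin_size and window_bp must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_chrom_sizes(indir: Path) -> Dict[str, int]:
    df = pd.read_csv(indir / "chrom_sizes.tsv", sep="\t", header=None,
                     names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to disk)."""
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "inputs": {}, "stages": {}}

    samples_tsv = indir / "samples.tsv"
    if not samples_tsv.exists():
        raise FileNotFoundError(f"missing {samples_tsv}")
    samples = pd.read_csv(samples_tsv, sep="\t")
    group_of = dict(zip(samples["Sample"].astype(str), samples["Group"].astype(str)))
    chrom_sizes = _read_chrom_sizes(indir)
    for p in sorted(indir.rglob("*")):
        if p.is_file():
            manifest["inputs"][str(p.relative_to(indir))] = _sha256(p)

    # --- stage: QC -------------------------------------------------------
    pair_tsv = indir / "pair_stats.tsv"
    if pair_tsv.exists():
        rows = qcmod.read_pair_stats(pair_tsv)
        summary = qcmod.summarize_qc(rows)
        (outdir / "qc_report.txt").write_text(qcmod.format_qc_report(summary))
        qcmod.write_pair_stats(rows, outdir / "qc_pair_stats.tsv")
        manifest["stages"]["qc"] = {
            "n_samples": len(rows),
            "mean_cis_ratio_pct": summary.mean_cis_ratio_pct,
            "median_valid_pairs": summary.median_valid_pairs,
        }
        log.info("qc: %d samples, mean cis ratio %.2f%%", len(rows),
                 summary.mean_cis_ratio_pct)

    # --- stage: boundary calling (or loading) ----------------------------
    per_sample: Dict[str, pd.DataFrame] = {}
    tracks: Dict[str, Dict[str, np.ndarray]] = {}
    mat_dir = indir / "matrices"
    bnd_dir = indir / "boundaries"
    bdir = outdir / "boundaries"
    bdir.mkdir(exist_ok=True)
    if mat_dir.exists():
        tad_rows = []
        balanced: Dict[str, Dict[str, object]] = {}
        for sample in group_of:
            calls = []
            segs = []
            tracks[sample] = {}
            for chrom in sorted(chrom_sizes):
                m = read_hicpro(mat_dir / f"{sample}.{chrom}.matrix",
                                mat_dir / f"{sample}.{chrom}.bed", chrom)
                mb = ice_balance(m)
                balanced.setdefault(sample, {})[chrom] = mb
                track = insulation_scores(mb, config.min_depth_bp,
                                          config.max_depth_bp, config.step_bp)
                b = call_boundaries(track, config.delta_min, config.call_fdr,
                                    sample=sample, group=group_of[sample])
                calls.append(b)
                segs.append(segment_tads(b, chrom, chrom_sizes[chrom]))
                tracks[sample][chrom] = track.delta
                iv.write_bedgraph(bdir / f"{sample}.{chrom}.bs.bedgraph", chrom,
                                  config.bin_size, track.delta)
            per_sample[sample] = pd.concat(calls, ignore_index=True)
            seg_all = pd.concat(segs, ignore_index=True)
            tad_rows.append(tad_summary(sample, config.bin_size, seg_all,
                                        per_sample[sample]))
            bed = per_sample[sample].copy()
            bed["name"] = sample
            bed["score"] = bed["strength"]
            iv.write_bed(bed, bdir / f"{sample}.boundaries.bed")
            iv.write_bed(seg_all.rename(columns={"size_bp": "score"})
                         .assign(name="tad"), outdir / f"tads_{sample}.bed",
                         cols=["chrom", "start", "end", "name", "score"])
        pd.DataFrame(tad_rows).to_csv(outdir / "tad_summary.tsv", sep="\t",
                                      index=False, float_format="%.3g")
        manifest["stages"]["tad_calling"] = {
            s: int(len(df)) for s, df in per_sample.items()}
        # replicate concordance (within group, per chromosome, Pearson log1p)
        corr_rows = []
        for group in sorted(set(group_of.values())):
            members = [s for s, g in group_of.items() if g == group]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    for chrom in sorted(chrom_sizes):
                        r = replicate_correlation(balanced[members[i]][chrom],
                                                  balanced[members[j]][chrom])
                        corr_rows.append({"group": group, "a": members[i],
                                          "b": members[j], "chrom": chrom,
                                          "pearson_log1p": r})
                        if np.isfinite(r) and r < config.concordance_min:
                            warnings.warn(
                                f"{members[i]} vs {members[j]} ({chrom}): "
                                f"correlation {r:.3f} below the "
                                f"{config.concordance_min} concordance bar")
        pd.DataFrame(corr_rows).to_csv(outdir / "replicate_correlation.tsv",
                                       sep="\t", index=False, float_format="%.4f")
    elif bnd_dir.exists():
        for sample in group_of:
            bed = iv.read_bed(bnd_dir / f"{sample}.boundaries.bed")
            bed["strength"] = bed["score"] if "score" in bed.columns else np.nan
            per_sample[sample] = bed
            tracks[sample] = {}
            bg_paths = sorted(bnd_dir.glob(f"{sample}.*.bs.bedgraph"))
            for p in bg_paths:
                bg = iv.read_bedgraph(p)
                for chrom, g in bg.groupby("chrom"):
                    n = int(np.ceil(chrom_sizes[chrom] / config.bin_size))
                    arr = np.full(n, np.nan)
                    arr[(g["start"] // config.bin_size).astype(int)] = g["value"]
                    tracks[sample][chrom] = arr
        manifest["stages"]["tad_calling"] = "skipped (boundaries supplied)"
    else:
        raise FileNotFoundError("input_dir must contain matrices/ or boundaries/")

    # --- stage: group comparison -----------------------------------------
    coll = cmp.BoundarySetCollection(per_sample=per_sample, group_of=group_of,
                                     bin_size=config.bin_size,
                                     tracks=tracks or None)
    summary = cmp.compare_groups(coll, config.specificity_tol_bp,
                                 config.pairing_window_bp, config.fdr_alpha)
    pairs, _ = cmp.delta_bs_test(coll, config.pairing_window_bp, config.fdr_alpha)
    cdir = outdir / "comparison"
    cdir.mkdir(exist_ok=True)
    pairs.to_csv(cdir / "delta_bs_pairs.tsv", sep="\t", index=False,
                 float_format="%.6g")
    ctrl_sp, under_sp, conserved = cmp.classify_specific(coll,
                                                         config.specificity_tol_bp)
    iv.write_bed(ctrl_sp, cdir / "ctrl_specific.bed")
    iv.write_bed(under_sp, cdir / "under_specific.bed")
    iv.write_bed(conserved, cdir / "conserved.bed")
    with open(cdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    manifest["stages"]["comparison"] = {k: summary[k] for k in
                                        ("jaccard", "n_ctrl_specific",
                                         "n_under_specific", "n_paired")}
    log.info("comparison: J=%.3f, %d CTRL-specific, %d UNDER-specific",
             summary["jaccard"], summary["n_ctrl_specific"],
             summary["n_under_specific"])

    # --- stage: hotspots and annotation ----------------------------------
    merged = {g: cmp.consensus(coll, g, "lenient") for g in ("CTRL", "UNDER")}
    windows = hs.boundary_density(merged, chrom_sizes, config.window_bp)
    under_hot, ctrl_hot = hs.detect_hotspots(windows, config.hotspot_delta_min)
    hdir = outdir / "hotspots"
    hdir.mkdir(exist_ok=True)
    genes = []
    if (indir / "genes.gff3").exists():
        genes = hs.read_genes_gff3(indir / "genes.gff3")
    table = hs.window_table(windows, genes) if genes else windows
    table.to_csv(hdir / "density_windows.tsv", sep="\t", index=False)
    for name, df in (("under_enriched", under_hot), ("ctrl_enriched", ctrl_hot)):
        iv.write_bed(df.rename(columns={"Chr": "chrom", "Start": "start",
                                        "End": "end"}),
                     hdir / f"{name}.bed", cols=["chrom", "start", "end"])
    regions = pd.concat([
        under_hot.rename(columns={"Chr": "chrom", "Start": "start", "End": "end"})
        [["chrom", "start", "end"]].assign(region_class="hotspot"),
        under_sp.assign(region_class="gain"),
        ctrl_sp.assign(region_class="loss"),
    ], ignore_index=True)
    dedup = {}
    ann_frames = []
    for cls, g in regions.groupby("region_class"):
        dd = hs.dedupe_regions(g, config.dedupe_bp)
        dedup[cls] = dd
        if genes:
            ann_frames.append(hs.annotate_regions(
                dd, genes, region_class=cls, promoter_pad=config.promoter_pad,
                tss_max=config.tss_max, tier3_max=config.tier3_max))
    if ann_frames:
        ann = pd.concat(ann_frames, ignore_index=True)
        ann.to_csv(hdir / "annotations.tsv", sep="\t", index=False)
    manifest["stages"]["hotspots"] = {
        "n_windows": int(len(windows)),
        "n_under_enriched": int(len(under_hot)),
        "n_ctrl_enriched": int(len(ctrl_hot)),
        "n_regions_annotated": int(sum(len(v) for v in dedup.values())),
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def make_demo(outdir, seed: int = 0) -> Path:
    """Write a complete synthetic study (2 CTRL + 2 UNDER) plus a ready config."""
    out = write_study(make_design(seed=seed), outdir)
    cfg = PipelineConfig(input_dir=str(out), output_dir=str(out / "results"),
                         seed=seed)
    cfg.to_yaml(out / "config.yaml")
    return out
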