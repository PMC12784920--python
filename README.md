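# tadscape

Differential TAD-boundary analysis for small case-control Hi-C studies.

`tadscape` asks a specific question of chromatin-conformation data: when two
groups of animals differ in a phenotype, is their 3D genome *globally*
reorganized, or is the TAD scaffold conserved with *localized* boundary
remodeling? It was built around a pilot design common in livestock and
disease genomics — two affected vs two control deep in situ Hi-C libraries
(the motivating case: mandibular prognathism in Dolang sheep, profiled in
mandibular bone at 40 kb resolution) — and packages every step from
valid-pair QC to annotated candidate loci as a tested, reusable library.

## What it computes

Given per-sample binned cis contact matrices (HiC-Pro `.matrix`/`.bed`
dialect or dense text):

1. **QC** — per-library cis ratio `100·cis/valid` and cohort summaries from
   valid-pair count tables.
2. **ICE balancing** — coverage-filtered (log-coverage z outside
   [−1.5, 5] masked) iterative correction to equal marginals.
3. **TAD/boundary calling** — multi-scale diamond insulation (windows
   ~40 kb–2 Mb), per-window z-scoring, TAD-separation score; boundaries are
   FDR-controlled local minima, with strength BS = the local insulation
   delta (z units, larger = stronger).
4. **Group comparison** — ±1-bin harmonization, lenient/stringent consensus,
   base-pair Jaccard `J = |A∩B|/|A∪B|`, nearest-boundary offsets,
   gain/loss classification at ±40 kb tolerance, and per-boundary
   `ΔBS = BS_case − BS_control` at loci paired within ±50 kb, tested across
   replicates (Welch) with Benjamini–Hochberg FDR.
5. **Hotspots & annotation** — 1 Mb boundary-density windows,
   `Δ = count_case − count_control`, hotspots at Δ ≥ 2; differential regions
   de-duplicated (±40 kb) and annotated with priority
   promoter (TSS ± 2 kb) > gene body > nearest TSS (≤ 1 Mb), tiers 1/2/3.
6. **Synthetic studies** — a generator that plants a known TAD scaffold,
   case-specific boundary gains, visibility bias and hotspot windows, so
   the whole pipeline can be validated against ground truth.

## Worked example

```python
import tadscape as ts
from tadscape.datasets import sheep_pair_stats

summary = ts.summarize_qc(sheep_pair_stats())
print(f"{summary.mean_cis_ratio_pct:.2f}")            # 54.86
print(f"{summary.median_valid_pairs / 1e6:.1f}")       # 463.1
```

The four-library ovine table gives a mean cis ratio of 54.86% (range
52.37–59.97%) and a median of 463.1 million valid pairs — deep,
ligation-dominated libraries suitable for 40 kb boundary analysis.

Running the comparison stage on a simulated study with six planted
case-specific boundaries (`python examples/03_compare_groups.py`) prints:

```
Jaccard J = 0.893 (2.00 / 2.24 Mb, 50 intersections)
nearest-boundary offsets: median 0 bp, 100.0% within one bin
specific boundaries: 0 CTRL, 6 UNDER (6 were planted in UNDER)
ΔBS: 50 paired boundaries, median +0.1085, 12 significant at FDR<0.10
```

High overlap with exactly the planted case-specific boundaries recovered is
the signature of a conserved scaffold with localized remodeling; the small
positive ΔBS median is a normalization side-effect of z-scored strength
tracks discussed in `docs/methods.md`.

The `examples/` directory holds one short script per capability (QC, TAD
calling, group comparison, hotspots/annotation, full pipeline), and a thin
CLI mirrors the pipeline:

```sh
tadscape simulate demo --seed 1     # write a synthetic study + config
tadscape run-all demo/config.yaml   # QC -> balance -> call -> compare -> hotspots
tadscape qc demo/pair_stats.tsv
```

## Layout

- `src/tadscape/` — the library (`qc`, `matrix`, `insulation`, `compare`,
  `hotspots`, `simulate`, `intervals`, `pipeline`, `cli`, `datasets`)
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, parameters, design choices, limitations
- `tests/` — unit, property and acceptance suites
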