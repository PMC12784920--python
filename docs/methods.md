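# Methods

`tadscape` implements the computational arc of a two-group (case vs control)
Hi-C comparison of TAD-boundary architecture, of the kind used to ask whether
a phenotype is accompanied by genome-wide reorganization of chromatin domains
or by localized boundary remodeling. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Pipeline model

The analysis consumes per-chromosome binned cis contact matrices (the working
resolution is 40 kb) and proceeds:

1. **QC.** Valid read pairs are partitioned into cis and trans; the
   per-library cis ratio `100·cis/valid` and cohort summaries (unweighted
   mean of per-sample ratios, median valid-pair count with the even-n
   midpoint) gate the libraries. Conservation `cis + trans = valid` is
   enforced, naming the offending sample on failure.

2. **ICE balancing.** Bins whose log10 coverage z-score falls outside
   `[-1.5, 5]` (or with zero coverage) are masked; iterative correction then
   equalizes unmasked marginals. Convergence is declared when the maximum
   relative deviation of marginals from their mean drops below `tol = 1e-5`
   (within `max_iter = 200`, else a warning and the best iterate). Total
   mass over unmasked bins is preserved, and weights satisfy
   `balanced[i,j] = raw[i,j]/(w_i·w_j)`. Balancing is defined only up to a
   global scale, so cross-matrix comparisons of absolute contact values are
   meaningful only after scale normalization.

3. **Insulation and boundary calling.** For each bin and a ladder of diamond
   windows (depths 250 bp to 2 Mb in 25 kb steps, each mapped to
   `max(1, round(depth/bin))` bins, so windows run from 1 to 50 bins at
   40 kb; the stated maximum depth is always included), the mean contact in
   the rectangle upstream-rows x downstream-columns is computed over
   unmasked bins via 2-D prefix sums. Each window's track is z-scored per
   chromosome, and the TAD-separation score is the mean z across windows.
   Note the tool the parameters come from rejects sub-3-bin minimum depths;
   recovery on synthetic data is indistinguishable between the 1-bin and
   6-bin (250 kb) readings, so the collapsed 1-bin minimum is kept as the
   default and `min_depth_bp` stays configurable.

   Boundary candidates are strict local minima of the separation score
   (leftmost on ties) whose local contrast
   `delta = mean(±10-bin flanks) − value` reaches `delta_min = 0.1`
   (z units). Candidates closer than 3 bins suppress each other, keeping
   the deeper trough: a masked bin can split one insulation trough into a
   double dip, and without suppression a single boundary would be called
   twice, two bins apart. Each surviving candidate is tested by a one-sided
   Wilcoxon rank-sum comparing its diamond contacts against the two flanking
   within-domain diamonds at a window of up to 5 bins, shrunk to half the
   distance to the nearest neighboring candidate so the "within-domain"
   reference does not itself straddle a boundary. Benjamini-Hochberg-adjusted
   q ≤ 0.05 calls are kept. Boundary strength (BS) is the delta at the
   minimum — larger means stronger insulation. **BS is in z-score units and
   is comparable within a run, not across tools**: external insulation
   callers report deltas on their own scales (published tables from such
   tools show magnitudes of ~0.02 where ours are ~1), and the sign/scale of
   those tools is not standardized.

4. **Group comparison.** Per-sample boundary intervals (single 40 kb bins)
   are harmonized by merging within ±1 bin. Group consensus sets are
   *lenient* (≥1 replicate) or *stringent* (every replicate within ±1 bin).
   Between groups we report: base-pair Jaccard `J = |A∩B|/|A∪B|` on merged
   sets (two empty sets give J = 1 with a degenerate flag, never NaN);
   nearest-midpoint offsets (ties to the smaller coordinate; median, mean,
   fractions within 1 and 2 bins); gain/loss classification (a case-specific
   boundary is a lenient-case interval with no control call from any
   replicate within ±40 kb, and conversely); and the ΔBS test. For ΔBS,
   boundaries are paired across groups by nearest midpoints within ±50 kb,
   greedily by ascending distance with each boundary used once; per paired
   locus, each replicate's BS is read from its delta track at that group's
   boundary bin, `ΔBS = mean(case) − mean(control)`, and a Welch t test
   across replicates (the two-sample collapse of a per-animal
   random-intercept model when each animal contributes one value per
   boundary) is BH-adjusted at FDR 0.10. Both pairing universes are
   available: group-merged consensus (default; non-redundant loci) and
   pooled per-replicate sets (a larger universe in which near-coincident
   replicate calls pair individually; measured to duplicate loci without
   changing the inference).

   A caveat surfaced by the simulator: because BS tracks are z-scored per
   sample, *adding* boundaries to one group shifts that group's whole
   normalized strength distribution, so shared boundaries acquire a small
   positive ΔBS in the remodeled group even though their physical contrast
   is unchanged. ΔBS should therefore be read alongside, not instead of,
   the gain/loss counts.

5. **Hotspots and annotation.** The genome is tiled into 1 Mb windows from
   coordinate 0 (short terminal tiles retained); group-merged boundaries are
   counted by midpoint, so every boundary lands in exactly one window, and
   `Δ = count_case − count_control`. Case-enriched hotspots have Δ ≥ 2
   (Δ ≥ 1 as a sensitivity mode). Differential regions (hotspot windows plus
   group-specific boundaries) are de-duplicated per chromosome with a
   ±40 kb merge and annotated with priority promoter (TSS ± 2 kb, clipped at
   chromosome bounds) > gene body > nearest TSS within ±1 Mb (distance as a
   half-open interval gap), tier 3 requiring ≤ 250 kb; ties resolve by TSS
   distance to the region midpoint, then gene id. TSS is strand-aware:
   `start` for +, `end − 1` for −, in 0-based half-open coordinates.

## Synthetic-data generator

The generator emulates the pilot study design: two groups x two replicates,
a TAD scaffold shared between groups, and a small number of case-only
boundaries that subdivide existing control domains.

- **Genome.** Two 20 Mb chromosomes at 40 kb bins by default — large enough
  for ~55 scaffold boundaries and stable summary statistics while keeping a
  full four-sample pipeline run in a few seconds.
- **Scaffold.** TAD sizes are lognormal with median 0.70 Mb (log-sd 0.35,
  clipped at 5 bins); boundaries are the cumulative breakpoints.
- **Contacts.** `E[c_ij] ∝ max(|i−j|, 0.5)^(−α) · (1 + β·same-TAD)` with
  α = 1 and β = 3, scaled so the full symmetric matrix sums to `depth`
  (default 2×10⁶ contacts per chromosome, i.e. 10⁶ per 10 Mb — the order of
  a few hundred million valid pairs spread over a mammalian genome).
  Adjacent domains share their boundary bin (two contact triangles touching
  at the boundary locus), which makes the boundary bin the unique insulation
  minimum; with disjoint domains the trough is two bins wide and calls
  jitter by one bin. Counts are Poisson draws on the upper triangle,
  mirrored; `replicate_noise > 0` switches to gamma-Poisson
  (negative-binomial) for between-replicate overdispersion.
- **Visibility bias.** A per-bin lognormal bias (sd 0.15) shared by all
  samples, with 3% of bins additionally scaled to 5-20% visibility,
  emulates mappability/restriction-density variation and the unmappable
  bins that the −1.5 coverage filter is meant to mask. ICE removes the
  bias; the filter masks essentially the bad bins.
- **Planted gains.** Six case-only boundaries by default: three in one chr1
  megabase tile (expected Δ = +3), two in one chr2 tile (Δ = +2), one
  isolated (below the hotspot threshold, exercising specificity). Gains are
  placed ≥ 4 bins from scaffold boundaries so that calls of a gain and of a
  control boundary, each up to ±1 bin off, can never fall within the 40 kb
  specificity tolerance of each other.
- **Pair counts and genes.** Valid pairs are Poisson around 5×10⁶ with cis
  drawn binomially at fraction 0.55 (cis + trans = valid by construction);
  genes are random strand-aware bodies (~2.5 per Mb, lognormal lengths),
  with every planted hotspot window guaranteed at least one overlapping
  gene.
- **Determinism.** One master seed; every artefact draws from a named
  substream (CRC-hashed label path), so samples, groups and chromosomes are
  independent and bit-reproducible.

What the generator does *not* emulate: A/B compartments, loops, restriction
-fragment structure, ligation artifacts, distance-decay curvature, nested/
overlapping domains, or cell-type mixtures. Passing recovery tests therefore
demonstrates the correctness of the pipeline's arithmetic and its behavior
under idealized block-TAD contrast — not calling performance on real tissue
Hi-C, where boundary contrast is weaker and heterogeneous.

## Validation strategy and problem sizes

- Interval primitives (merge, Jaccard, nearest, annotation) are tested
  against brute-force position-set oracles on 1000 randomized cases each.
- Diamond means match a nested-loop oracle exactly on matrices up to 50
  bins.
- Parameter recovery runs the full 2×20 Mb, 2v2 study at default depth:
  per-sample boundary recall ≥ 90% within ±1 bin, every planted hotspot
  window detected at Δ ≥ 2, and the planted gains recovered exactly by the
  specificity classifier.
- Null behavior runs 100 seeded no-gain studies: the grand median of
  per-run ΔBS medians lies within ±0.01 of 0, and ≥ 95% of runs yield zero
  FDR < 0.10 discoveries. Per-run medians fluctuate with an irreducible
  se ≈ 0.007 (≈ 1.25·σ_pair/√n at ~53 pairs per run), so the centering
  claim is about the ensemble, not single realizations.
- The ICE contract is checked as marginal equality to 1e-5 relative
  tolerance and distance-decay invariance (≤ 2% after scale normalization)
  under injected per-bin bias.

## Known limitations

- BS/ΔBS are z-scale quantities; absolute values are not portable across
  callers, and cross-group normalization coupling (above) biases ΔBS
  slightly positive in a group that gained boundaries.
- Welch's t on two replicates per group has very low power; the ΔBS stage
  is a screening device, as in the pilot design it mirrors.
- The caller assumes clean block contrast; nested sub-TADs or gradual
  boundaries will blur the separation-score minima.
- Matrices are dense per chromosome; at bin counts ≫ 10⁴ per chromosome a
  sparse backend would be needed.
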