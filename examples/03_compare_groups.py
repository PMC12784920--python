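"""Two-group boundary comparison with planted case-specific boundaries.

Simulates the full 2 CTRL vs 2 UNDER study (shared TAD scaffold, six
boundaries present only in the case group), calls boundaries per replicate,
and runs the comparison stage: base-pair Jaccard overlap, nearest-boundary
offsets, gain/loss classification under a ±40 kb tolerance, and the
per-boundary ΔBS test with BH-FDR control.
"""

import pandas as pd

import tadscape as ts
from tadscape import compare as cmp

design = ts.make_design(seed=1)

per_sample, tracks, group_of = {}, {}, {}
for sample, group, rep in design.samples():
    group_of[sample] = group
    tracks[sample] = {}
    calls = []
    for chrom in design.chrom_sizes:
        m = ts.ice_balance(ts.simulate_contact_matrix(design, group, rep, chrom))
        tr = ts.insulation_scores(m)
        calls.append(ts.call_boundaries(tr, sample=sample, group=group))
        tracks[sample][chrom] = tr.delta
    per_sample[sample] = pd.concat(calls, ignore_index=True)

coll = cmp.BoundarySetCollection(per_sample=per_sample, group_of=group_of,
                                 bin_size=design.bin_size, tracks=tracks)
summary = ts.compare_groups(coll)

print(f"Jaccard J = {summary['jaccard']:.3f} "
      f"({summary['intersect_bp'] / 1e6:.2f} / {summary['union_bp'] / 1e6:.2f} Mb, "
      f"{summary['n_intersections']} intersections)")
print(f"nearest-boundary offsets: median {summary['offset_median_bp']:.0f} bp, "
      f"{100 * summary['frac_within_1bin']:.1f}% within one bin")
print(f"specific boundaries: {summary['n_ctrl_specific']} CTRL, "
      f"{summary['n_under_specific']} UNDER (6 were planted in UNDER)")
print(f"ΔBS: {summary['n_paired']} paired boundaries, "
      f"median {summary['delta_bs_median']:+.4f}, "
      f"{summary['n_significant']} significant at FDR<0.10")
print()
print("High J with zero CTRL-specific and exactly the planted UNDER-specific")
print("boundaries is the signature of a conserved scaffold with localized")
print("case-specific gains.  Note the positive ΔBS median: because the BS")
print("track is z-scored per sample, adding boundaries to the case group")
print("shifts its whole normalized strength distribution slightly, so shared")
print("boundaries look marginally stronger -- a scale effect to keep in mind")
print("when interpreting ΔBS alongside gain/loss counts (with no planted")
print("gains the ΔBS median is zero and no boundary reaches FDR < 0.10).")
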