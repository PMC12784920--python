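"""Group-wise boundary comparison: harmonize, consensus, specificity, ΔBS."""

import numpy as np
import pandas as pd
import pytest

import tadscape as ts
from tadscape import compare as cmp
from tadscape import intervals as iv

BIN = 40_000


def calls(*positions, chrom="chr1"):
    return iv.as_intervals([(chrom, p, p + BIN) for p in positions])


def collection(per_sample, group_of, tracks=None):
    return cmp.BoundarySetCollection(per_sample=per_sample, group_of=group_of,
                                     bin_size=BIN, tracks=tracks)


class TestHarmonize:
    def test_adjacent_bins_merge(self):
        got = ts.harmonize(calls(120_000, 160_000), BIN)
        assert got.values.tolist() == [["chr1", 120_000, 200_000]]

    def test_one_bin_gap_merges(self):
        got = ts.harmonize(calls(0, 80_000), BIN)
        assert got.values.tolist() == [["chr1", 0, 120_000]]

    def test_far_apart_untouched(self):
        assert len(ts.harmonize(calls(0, 200_000), BIN)) == 2

    def test_idempotent(self):
        x = calls(0, 40_000, 200_000, 400_000, 440_000)
        once = ts.harmonize(x, BIN)
        assert ts.harmonize(once, BIN).equals(once)


class TestConsensus:
    def test_identical_replicates_lenient_equals_stringent(self):
        coll = collection({"a": calls(0, 200_000), "b": calls(0, 200_000)},
                          {"a": "CTRL", "b": "CTRL"})
        lenient = ts.consensus(coll, "CTRL", "lenient")
        stringent = ts.consensus(coll, "CTRL", "stringent")
        assert lenient.equals(stringent)
        assert len(lenient) == 2

    def test_private_boundary_only_in_lenient(self):
        coll = collection({"a": calls(0, 400_000), "b": calls(0)},
                          {"a": "CTRL", "b": "CTRL"})
        lenient = ts.consensus(coll, "CTRL", "lenient")
        stringent = ts.consensus(coll, "CTRL", "stringent")
        assert len(lenient) == 2 and len(stringent) == 1

    def test_one_bin_offset_counts_as_support(self):
        coll = collection({"a": calls(400_000), "b": calls(440_000)},
                          {"a": "CTRL", "b": "CTRL"})
        stringent = ts.consensus(coll, "CTRL", "stringent")
        assert stringent.values.tolist() == [["chr1", 400_000, 480_000]]

    def test_unknown_group_rejected(self):
        coll = collection({"a": calls(0)}, {"a": "CTRL"})
        with pytest.raises(ValueError):
            ts.consensus(coll, "UNDER")


class TestClassifySpecific:
    def test_case_only_boundary_is_case_specific(self):
        coll = collection(
            {"c1": calls(0), "c2": calls(0),
             "u1": calls(0, 400_000), "u2": calls(0, 400_000)},
            {"c1": "CTRL", "c2": "CTRL", "u1": "UNDER", "u2": "UNDER"})
        ctrl_sp, under_sp, conserved = ts.classify_specific(coll, 40_000)
        assert len(ctrl_sp) == 0
        assert under_sp.values.tolist() == [["chr1", 400_000, 440_000]]
        assert conserved.values.tolist() == [["chr1", 0, 40_000]]

    def test_single_replicate_support_suffices(self):
        # lenient >= 1-replicate rule: present in one case replicate only
        coll = collection(
            {"c1": calls(), "c2": calls(), "u1": calls(400_000), "u2": calls()},
            {"c1": "CTRL", "c2": "CTRL", "u1": "UNDER", "u2": "UNDER"})
        _, under_sp, _ = ts.classify_specific(coll, 40_000)
        assert len(under_sp) == 1

    def test_nearby_other_group_boundary_blocks_specificity(self):
        coll = collection(
            {"c1": calls(360_000), "c2": calls(),
             "u1": calls(400_000), "u2": calls(400_000)},
            {"c1": "CTRL", "c2": "CTRL", "u1": "UNDER", "u2": "UNDER"})
        _, under_sp, _ = ts.classify_specific(coll, 40_000)
        assert len(under_sp) == 0  # CTRL call 40 kb away, within tolerance

    def test_negative_tolerance_rejected(self):
        coll = collection({"a": calls(0), "b": calls(0)},
                          {"a": "CTRL", "b": "UNDER"})
        with pytest.raises(ValueError):
            ts.classify_specific(coll, -1)

    def test_planted_gains_recovered_exactly(self, planted_design,
                                             planted_collection):
        """Every planted case-specific boundary is recovered within one bin
        and no spurious case-specific boundaries appear."""
        _, under_sp, _ = ts.classify_specific(planted_collection, 40_000)
        gains = planted_design.planted_gains
        assert len(under_sp) == len(gains)
        for chrom, pos in gains:
            g = under_sp[under_sp["chrom"] == chrom]
            mid = iv.midpoints(g)
            assert (np.abs(mid - (pos + planted_design.bin_size / 2))
                    <= planted_design.bin_size).any()


class TestDeltaBS:
    def tracks_for(self, values_by_sample, n=30):
        out = {}
        for s, pairs in values_by_sample.items():
            arr = np.zeros(n)
            for b, v in pairs:
                arr[b] = v
            out[s] = {"chr1": arr}
        return out

    def make_coll(self, ctrl_bs, under_bs, pos=400_000):
        b = pos // BIN
        per = {"c1": calls(pos), "c2": calls(pos),
               "u1": calls(pos), "u2": calls(pos)}
        tracks = self.tracks_for({
            "c1": [(b, ctrl_bs[0])], "c2": [(b, ctrl_bs[1])],
            "u1": [(b, under_bs[0])], "u2": [(b, under_bs[1])]})
        return collection(per, {"c1": "CTRL", "c2": "CTRL",
                                "u1": "UNDER", "u2": "UNDER"}, tracks)

    def test_group_median_subtraction(self):
        # published group medians: BS_UNDER −0.016, BS_CTRL −0.022 -> ΔBS +0.006
        coll = self.make_coll(ctrl_bs=(-0.022, -0.022), under_bs=(-0.016, -0.016))
        pairs, _ = ts.delta_bs_test(coll)
        assert pairs.loc[0, "delta_bs"] == pytest.approx(0.006)

    def test_identical_groups_null(self):
        coll = self.make_coll(ctrl_bs=(0.5, 0.6), under_bs=(0.5, 0.6))
        pairs, summary = ts.delta_bs_test(coll)
        assert summary["delta_bs_median"] == 0.0
        assert summary["n_significant"] == 0

    def test_label_swap_antisymmetry(self, null_collection):
        pairs, s1 = ts.delta_bs_test(null_collection)
        swapped = cmp.BoundarySetCollection(
            per_sample=null_collection.per_sample,
            group_of={k: ("CTRL" if v == "UNDER" else "UNDER")
                      for k, v in null_collection.group_of.items()},
            bin_size=null_collection.bin_size, tracks=null_collection.tracks)
        pairs2, s2 = ts.delta_bs_test(swapped)
        assert s1["n_paired"] == s2["n_paired"]
        assert s1["delta_bs_median"] == pytest.approx(-s2["delta_bs_median"])
        assert s1["median_abs_delta_bs"] == pytest.approx(s2["median_abs_delta_bs"])
        q1 = np.sort(pairs["q_value"].to_numpy())
        q2 = np.sort(pairs2["q_value"].to_numpy())
        np.testing.assert_allclose(q1, q2)

    def test_pairing_window_respected(self):
        per = {"c1": calls(0), "c2": calls(0),
               "u1": calls(120_000), "u2": calls(120_000)}
        tracks = self.tracks_for({"c1": [(0, 1.0)], "c2": [(0, 1.0)],
                                  "u1": [(3, 1.0)], "u2": [(3, 1.0)]})
        coll = collection(per, {"c1": "CTRL", "c2": "CTRL",
                                "u1": "UNDER", "u2": "UNDER"}, tracks)
        _, s_narrow = ts.delta_bs_test(coll, pairing_window_bp=50_000)
        _, s_wide = ts.delta_bs_test(coll, pairing_window_bp=200_000)
        assert s_narrow["n_paired"] == 0 and s_wide["n_paired"] == 1

    def test_missing_tracks_rejected(self):
        coll = collection({"a": calls(0), "b": calls(0)},
                          {"a": "CTRL", "b": "UNDER"})
        with pytest.raises(ValueError, match="tracks"):
            ts.delta_bs_test(coll)

    def test_replicate_universe_is_larger(self, planted_collection):
        _, sg = ts.delta_bs_test(planted_collection, universe="group")
        _, sr = ts.delta_bs_test(planted_collection, universe="replicate")
        assert sr["n_paired"] >= sg["n_paired"]


class TestBenjaminiHochberg:
    def test_empirical_fdr_on_uniform_null(self, rng):
        """BH at 10% on uniform-null p-values keeps false-discovery runs rare."""
        from statsmodels.stats.multitest import multipletests
        n_boundaries, n_reps = 1000, 500
        n_false = 0
        for _ in range(n_reps):
            p = rng.random(n_boundaries)
            rej, *_ = multipletests(p, alpha=0.10, method="fdr_bh")
            n_false += rej.any()
        # under the global null, P(any BH discovery) = alpha = 0.10
        assert n_false / n_reps <= 0.10 + 3 * np.sqrt(0.1 * 0.9 / n_reps)


def test_compare_groups_summary_keys(planted_collection):
    out = ts.compare_groups(planted_collection)
    for key in ("jaccard", "intersect_bp", "union_bp", "n_intersections",
                "n_ctrl_specific", "n_under_specific", "offset_median_bp",
                "n_paired", "delta_bs_median"):
        assert key in out
    assert 0 <= out["jaccard"] <= 1
    assert out["intersect_bp"] <= out["union_bp"]
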