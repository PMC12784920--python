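"""Density windows, hotspot rule, region de-dup, and tiered gene annotation."""

import numpy as np
import pandas as pd
import pytest

import tadscape as ts
from tadscape import hotspots as hs
from tadscape import intervals as iv
from tadscape.datasets import sheep_density_windows


def boundaries(*positions, chrom="chr1", width=40_000):
    return iv.as_intervals([(chrom, p, p + width) for p in positions])


class TestBoundaryDensity:
    SIZES = {"chr1": 3_500_000}

    def test_counts_and_delta(self):
        win = ts.boundary_density(
            {"CTRL": boundaries(), "UNDER": boundaries(100_000, 400_000, 800_000)},
            self.SIZES)
        assert win.loc[0, ["Count_CTRL", "Count_UNDER", "Delta"]].tolist() == [0, 3, 3]

    def test_empty_everywhere(self):
        win = ts.boundary_density({"CTRL": boundaries(), "UNDER": boundaries()},
                                  self.SIZES)
        assert (win["Delta"] == 0).all() and len(win) == 4

    def test_delta_sum_conservation(self, rng):
        """Sum of Δ equals total UNDER minus total CTRL boundaries."""
        for _ in range(20):
            pc = rng.integers(0, 3_400_000, size=rng.integers(0, 12))
            pu = rng.integers(0, 3_400_000, size=rng.integers(0, 12))
            win = ts.boundary_density({"CTRL": boundaries(*pc),
                                       "UNDER": boundaries(*pu)}, self.SIZES)
            assert win["Delta"].sum() == len(pu) - len(pc)
            assert win["Count_CTRL"].sum() == len(pc)  # partition: counted once

    def test_terminal_short_tile_retained(self):
        win = ts.boundary_density({"CTRL": boundaries(), "UNDER": boundaries()},
                                  self.SIZES)
        assert win.iloc[-1]["End"] - win.iloc[-1]["Start"] == 500_000

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            ts.boundary_density({}, self.SIZES, window_bp=0)


class TestDetectHotspots:
    def test_published_windows_all_flagged(self):
        tbl = sheep_density_windows()
        tbl["Delta"] = tbl["Count_UNDER"] - tbl["Count_CTRL"]
        under, ctrl = ts.detect_hotspots(tbl, delta_min=2)
        assert len(under) == 5 and len(ctrl) == 0
        assert tbl["Delta"].tolist() == [3, 2, 2, 2, 2]

    def test_threshold_boundary_cases(self):
        win = pd.DataFrame({"Chr": ["c"] * 3, "Start": [0, 1, 2],
                            "End": [1, 2, 3], "Count_CTRL": [0, 0, 3],
                            "Count_UNDER": [1, 2, 0], "Delta": [1, 2, -3]})
        u2, c2 = ts.detect_hotspots(win, 2)
        assert u2["Delta"].tolist() == [2] and c2["Delta"].tolist() == [-3]
        u1, _ = ts.detect_hotspots(win, 1)
        assert u1["Delta"].tolist() == [1, 2]

    def test_stringent_subset_of_sensitive(self, rng):
        win = pd.DataFrame({"Chr": "c", "Start": range(50), "End": range(1, 51),
                            "Count_CTRL": rng.integers(0, 4, 50),
                            "Count_UNDER": rng.integers(0, 4, 50)})
        win["Delta"] = win["Count_UNDER"] - win["Count_CTRL"]
        u2, _ = ts.detect_hotspots(win, 2)
        u1, _ = ts.detect_hotspots(win, 1)
        assert set(u2["Start"]) <= set(u1["Start"])


class TestDedupe:
    def test_edge_sharing_windows_merge(self):
        r = iv.as_intervals([("c", 0, 1_000_000), ("c", 1_000_000, 2_000_000)])
        assert len(ts.dedupe_regions(r)) == 1

    def test_distant_regions_kept(self):
        r = iv.as_intervals([("c", 0, 10_000), ("c", 110_000, 120_000)])
        assert len(ts.dedupe_regions(r, merge_bp=40_000)) == 2

    def test_idempotent(self, rng):
        starts = rng.integers(0, 5_000_000, 30)
        r = iv.as_intervals([("c", int(s), int(s) + 40_000) for s in starts])
        once = ts.dedupe_regions(r)
        assert ts.dedupe_regions(once).equals(once)


class TestGeneModel:
    def test_tss_strand_rule(self):
        assert hs.GeneModel("g", "chr1", 100, 500, "+").tss == 100
        assert hs.GeneModel("g", "chr1", 100, 500, "-").tss == 499

    def test_promoter_clipped_at_origin(self):
        g = hs.GeneModel("g", "chr1", 500, 900, "+")
        lo, hi = g.promoter(2_000)
        assert lo == 0 and hi == 2_501

    def test_degenerate_body_rejected(self):
        with pytest.raises(ValueError):
            hs.GeneModel("g", "chr1", 100, 100, "+")


class TestAnnotateRegion:
    GENES = [
        hs.GeneModel("geneA", "chr1", 100_000, 140_000, "+"),
        hs.GeneModel("geneB", "chr1", 90_000, 200_000, "-"),
    ]

    def test_promoter_beats_gene_body(self):
        # region covers geneA's promoter and geneB's body
        ann = ts.annotate_region("chr1", 99_000, 103_000, self.GENES)
        assert (ann.relation, ann.gene_id, ann.tier, ann.distance_bp) == \
            ("promoter", "geneA", 1, 0)

    def test_gene_body_tier2(self):
        ann = ts.annotate_region("chr1", 150_000, 160_000,
                                 [self.GENES[0],
                                  hs.GeneModel("geneC", "chr1", 145_000, 170_000, "+")])
        assert (ann.relation, ann.gene_id, ann.tier) == ("gene_body", "geneC", 2)

    def test_nearest_tss_beyond_tier3_cutoff(self):
        genes = [hs.GeneModel("far", "chr1", 600_000, 650_000, "+")]
        ann = ts.annotate_region("chr1", 0, 300_000, genes)
        assert (ann.relation, ann.distance_bp, ann.tier) == \
            ("nearest_tss", 300_000, None)

    def test_nearest_tss_within_tier3(self):
        genes = [hs.GeneModel("near", "chr1", 400_000, 450_000, "+")]
        ann = ts.annotate_region("chr1", 0, 300_000, genes)
        assert (ann.tier, ann.distance_bp) == (3, 100_000)

    def test_no_gene_within_1mb(self):
        genes = [hs.GeneModel("veryfar", "chr1", 2_000_000, 2_050_000, "+")]
        ann = ts.annotate_region("chr1", 0, 300_000, genes)
        assert ann.gene_id is None and ann.tier is None

    def test_gene_order_invariance(self, rng):
        genes = list(self.GENES)
        ann1 = ts.annotate_region("chr1", 95_000, 105_000, genes)
        ann2 = ts.annotate_region("chr1", 95_000, 105_000, genes[::-1])
        assert ann1 == ann2

    def test_randomized_against_exhaustive_oracle(self, rng):
        """Vectorized-ish annotation matches a literal re-reading of the rule."""
        for _ in range(300):
            genes = []
            for k in range(rng.integers(0, 8)):
                s = int(rng.integers(0, 2_000_000))
                genes.append(hs.GeneModel(f"g{k}", "chr1", s,
                                          s + int(rng.integers(1_000, 120_000)),
                                          "+" if rng.random() < 0.5 else "-"))
            start = int(rng.integers(0, 2_000_000))
            end = start + int(rng.integers(10_000, 1_000_000))
            ann = ts.annotate_region("chr1", start, end, genes)
            mid = (start + end) / 2

            def overlaps(a0, a1, b0, b1):
                return max(a0, b0) < min(a1, b1)

            prom = [g for g in genes
                    if overlaps(start, end, max(0, g.tss - 2_000), g.tss + 2_001)]
            body = [g for g in genes if overlaps(start, end, g.start, g.end)]
            if prom:
                best = min(prom, key=lambda g: (abs(g.tss - mid), g.gene_id))
                assert (ann.relation, ann.gene_id, ann.tier) == \
                    ("promoter", best.gene_id, 1)
            elif body:
                best = min(body, key=lambda g: (abs(g.tss - mid), g.gene_id))
                assert (ann.relation, ann.gene_id, ann.tier) == \
                    ("gene_body", best.gene_id, 2)
            else:
                dists = [(max(start - (g.tss + 1), g.tss - end, 0), g.gene_id, g)
                         for g in genes]
                dists = [d for d in dists if d[0] <= 1_000_000]
                if not dists:
                    assert ann.gene_id is None
                else:
                    d, gid, _ = min(dists)
                    assert (ann.relation, ann.gene_id, ann.distance_bp) == \
                        ("nearest_tss", gid, d)
                    assert ann.tier == (3 if d <= 250_000 else None)


class TestGeneIO:
    def test_gff3_round_trip(self, tmp_path):
        genes = [hs.GeneModel("a", "chr1", 0, 500, "+"),
                 hs.GeneModel("b", "chr2", 100, 900, "-")]
        hs.write_genes_gff3(genes, tmp_path / "g.gff3")
        assert hs.read_genes_gff3(tmp_path / "g.gff3") == genes

    def test_bed6(self, tmp_path):
        (tmp_path / "g.bed").write_text("chr1\t10\t50\tmygene\t0\t-\n")
        genes = hs.read_genes_bed(tmp_path / "g.bed")
        assert genes[0].gene_id == "mygene" and genes[0].tss == 49

    def test_bed_without_strand_rejected(self, tmp_path):
        (tmp_path / "g.bed").write_text("chr1\t10\t50\n")
        with pytest.raises(ValueError):
            hs.read_genes_bed(tmp_path / "g.bed")


def test_window_gene_table():
    genes = [hs.GeneModel("inwin", "chr1", 150_000, 220_000, "+"),
             hs.GeneModel("outside", "chr1", 3_000_000, 3_100_000, "+")]
    win = ts.boundary_density({"CTRL": boundaries(), "UNDER": boundaries(160_000)},
                              {"chr1": 4_000_000})
    tbl = hs.window_table(win, genes)
    assert tbl.loc[0, "Genes"] == "inwin"
    assert tbl.loc[3, "Genes"] == "outside"
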