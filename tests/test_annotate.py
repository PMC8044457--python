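"""Nearest-feature search, DMR classification and count matrices."""

import numpy as np
import pandas as pd
import pytest

from methylgen.annotate import (FeatureIndex, annotate_dmrs,
                                classification_count_matrix, classify_dmr,
                                interval_distance, is_upstream,
                                nearest_feature)
from methylgen.types import Feature


def gene(start, end, strand="+", gid="g", chrom="c"):
    return Feature(chrom, start, end, strand, gid, "gene")


def brute_force_nearest(region, features):
    chrom, start, end = region
    cands = [(interval_distance(start, end, f.start, f.end), f.start, f.id, f)
             for f in features if f.chrom == chrom]
    if not cands:
        return None
    return min(cands)[3]


class TestIntervalDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ((100, 200), (300, 500), 100),
        ((100, 200), (150, 400), 0),    # overlap
        ((100, 200), (0, 50), 50),
        ((0, 100), (100, 200), 0),      # abutting half-open intervals
    ])
    def test_gap(self, a, b, expected):
        assert interval_distance(*a, *b) == expected


class TestNearest:
    def test_nearest_of_two(self):
        hit = nearest_feature(("c", 100, 200),
                              [gene(300, 500, gid="a"), gene(600, 700, gid="b")])
        assert hit.feature.id == "a" and hit.distance == 100
        assert hit.position == "right"

    def test_overlap_distance_zero(self):
        hit = nearest_feature(("c", 100, 200), [gene(150, 400)])
        assert hit.distance == 0 and hit.position == "overlap"

    def test_tie_broken_by_start(self):
        hit = nearest_feature(("c", 100, 200),
                              [gene(250, 300, gid="right"),
                               gene(0, 50, gid="left")])
        assert hit.distance == 50 and hit.feature.id == "left"

    def test_no_feature_on_chromosome(self):
        assert nearest_feature(("c", 0, 10), [gene(0, 10, chrom="d")]) is None

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        features = []
        for i in range(200):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 100_000))
            length = int(rng.integers(1, 5_000))
            features.append(Feature(chrom, start, start + length, "+",
                                    f"f{i:03d}", "gene"))
        index = FeatureIndex(features)
        for _ in range(1000):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 105_000))
            region = (chrom, start, start + int(rng.integers(1, 3_000)))
            expected = brute_force_nearest(region, features)
            got = index.nearest(*region)
            assert got.feature == expected
            assert got.distance == interval_distance(
                region[1], region[2], expected.start, expected.end)


class TestClassify:
    def test_upstream_of_plus_gene_is_promoter(self):
        g = gene(300, 500, "+")
        hit = nearest_feature(("c", 0, 150), [g])
        assert hit.distance == 150
        assert classify_dmr(("c", 0, 150), hit, None) == {"promoter"}

    def test_downstream_of_plus_gene_is_not_promoter(self):
        g = gene(300, 500, "+")
        hit = nearest_feature(("c", 520, 600), [g])
        assert hit.distance == 20
        assert classify_dmr(("c", 520, 600), hit, None) == set()

    def test_downstream_region_is_upstream_of_minus_gene(self):
        g = gene(300, 500, "-")
        hit = nearest_feature(("c", 520, 600), [g])
        assert classify_dmr(("c", 520, 600), hit, None) == {"promoter"}

    def test_beyond_two_kb_not_promoter(self):
        g = gene(5000, 6000, "+")
        hit = nearest_feature(("c", 0, 100), [g])
        assert hit.distance == 4900
        assert classify_dmr(("c", 0, 100), hit, None) == set()

    def test_overlap_is_gene_body_never_promoter(self):
        g = gene(300, 500, "+")
        hit = nearest_feature(("c", 400, 600), [g])
        assert classify_dmr(("c", 400, 600), hit, None) == {"gene_body"}

    def test_te_overlap(self):
        te = Feature("c", 100, 300, ".", "TE1", "TE")
        hit = nearest_feature(("c", 200, 250), [te])
        assert classify_dmr(("c", 200, 250), None, hit) == {"te"}

    def test_promoter_and_gene_body_mutually_exclusive_randomized(self):
        rng = np.random.default_rng(5)
        genes = [gene(int(s), int(s) + int(rng.integers(100, 2000)),
                      "+" if rng.random() < 0.5 else "-", f"g{i}")
                 for i, s in enumerate(rng.integers(0, 50_000, size=30))]
        tes = [Feature("c", int(s), int(s) + 300, ".", f"t{i}", "TE")
               for i, s in enumerate(rng.integers(0, 50_000, size=10))]
        gi, ti = FeatureIndex(genes), FeatureIndex(tes)
        for _ in range(300):
            start = int(rng.integers(0, 52_000))
            region = ("c", start, start + 1000)
            classes = classify_dmr(region, gi.nearest(*region),
                                   ti.nearest(*region))
            assert not ({"promoter", "gene_body"} <= classes)

    def test_translation_invariance(self):
        g, te = gene(300, 500, "+"), Feature("c", 800, 900, ".", "t", "TE")
        for shift in (0, 1234, 50_000):
            gs = Feature("c", g.start + shift, g.end + shift, "+", "g", "gene")
            ts = Feature("c", te.start + shift, te.end + shift, ".", "t", "TE")
            region = ("c", 0 + shift, 150 + shift)
            classes = classify_dmr(region, nearest_feature(region, [gs]),
                                   nearest_feature(region, [ts]))
            assert classes == {"promoter"}

    def test_strandless_gene_falls_back_to_left_of_start(self):
        g = gene(300, 500, ".")
        hit = nearest_feature(("c", 0, 150), [g])
        assert is_upstream(0, 150, g)
        assert classify_dmr(("c", 0, 150), hit, None) == {"promoter"}


def dmr_frame(rows):
    cols = ["comparison", "axis", "chrom", "start", "end", "context",
            "level_a", "level_b", "difference", "p_raw", "p_adj",
            "direction", "n_sites_tested"]
    return pd.DataFrame(rows, columns=cols)


def dmr_row(start, end, direction="hyper", comp="A_vs_B", context="CG"):
    return (comp, "intragenerational", "c", start, end, context,
            0.3, 0.6, 0.3, 1e-4, 1e-3, direction, 8)


class TestAnnotateAndCount:
    genes = [gene(3000, 5000, "+", "g1"), gene(9000, 12000, "-", "g2")]
    tes = [Feature("c", 4500, 4800, ".", "t1", "TE")]

    def test_annotation_columns(self):
        dmrs = dmr_frame([dmr_row(1500, 2500)])
        ann = annotate_dmrs(dmrs, self.genes, self.tes)
        row = ann.iloc[0]
        assert row["nearest_gene"] == "g1"
        assert row["gene_distance"] == 500
        assert row["classes"] == "promoter"

    def test_two_promoter_dmrs_count_one_gene(self):
        dmrs = dmr_frame([dmr_row(1500, 2000), dmr_row(2200, 2700)])
        ann = annotate_dmrs(dmrs, self.genes, self.tes)
        mat = classification_count_matrix(ann)
        assert mat["promoter"].iloc[0] == 1

    def test_gene_and_te_overlap_counted_in_both(self):
        dmrs = dmr_frame([dmr_row(4400, 4600)])
        ann = annotate_dmrs(dmrs, self.genes, self.tes)
        mat = classification_count_matrix(ann)
        assert mat["gene_body"].iloc[0] == 1 and mat["te"].iloc[0] == 1

    def test_empty_input_zero_matrix(self):
        mat = classification_count_matrix(dmr_frame([]))
        assert mat.empty
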