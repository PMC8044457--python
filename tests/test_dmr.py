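"""Comparison design, region definition, testing, BH and DMR filters."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from methylgen.dmr import (adjust_pvalues, call_dmrs, define_regions,
                           dmr_count_matrix, enumerate_comparisons,
                           region_level)
from methylgen.dmr import test_all_regions as run_all_region_tests
from methylgen.dmr import test_region as run_region_test
from methylgen.types import (INTERGENERATIONAL, INTRAGENERATIONAL,
                             ComparisonSpec, DMRParams)


class TestComparisonDesign:
    def test_full_design_yields_18_sets(self):
        comps = enumerate_comparisons(["P0", "S1", "S2"], ["g0", "g30", "g110"])
        assert len(comps) == 18
        assert sum(c.axis == INTRAGENERATIONAL for c in comps) == 9
        assert sum(c.axis == INTERGENERATIONAL for c in comps) == 9

    def test_two_by_two_design(self):
        comps = enumerate_comparisons(["P0", "S1"], ["g0", "g30"])
        assert len(comps) == 4

    def test_single_generation_intra_only(self):
        comps = enumerate_comparisons(["S1"], ["g0", "g30", "g110"])
        assert len(comps) == 3
        assert all(c.axis == INTRAGENERATIONAL for c in comps)

    def test_ordering_earlier_condition_first(self):
        comps = enumerate_comparisons(["P0", "S1", "S2"], ["g0", "g30", "g110"])
        labels = {c.label for c in comps}
        assert "P0g0_vs_P0g30" in labels and "P0g30_vs_P0g0" not in labels
        assert "P0g30_vs_S1g30" in labels

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            enumerate_comparisons(["P0"], ["g0"])

    def test_unique_labels(self):
        comps = enumerate_comparisons(["P0", "S1", "S2"], ["g0", "g30", "g110"])
        assert len({c.label for c in comps}) == 18


class TestRegions:
    def test_tiling_with_partial_last(self):
        regions = define_regions({"c": 2500}, DMRParams(window_size=1000))
        assert list(zip(regions["start"], regions["end"])) == [
            (0, 1000), (1000, 2000), (2000, 2500)]

    def test_overlapping_windows(self):
        params = DMRParams(window_size=1000, window_step=500)
        regions = define_regions({"c": 3000}, params)
        # ceil((L - size) / step) + 1 = ceil(2000/500)+1 = 5
        assert len(regions) == 5
        assert regions["start"].tolist() == [0, 500, 1000, 1500, 2000]

    def test_empty_chromosome_no_tiles(self):
        assert define_regions({"c": 0}, DMRParams()).empty


class TestRegionLevel:
    def make(self, counts, context="CG"):
        rows = [("c", i, "+", mc, uc, context, "CGA")
                for i, (mc, uc) in enumerate(counts)]
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mc",
                                           "uc", "context", "tri"])

    def test_coverage_filter_and_pooling(self):
        s = self.make([(3, 2), (1, 4)])
        level = region_level(s, ("c", 0, 10), "CG",
                             DMRParams(min_site_coverage=5))
        assert level == pytest.approx(0.4)

    def test_all_sites_below_coverage_undefined(self):
        s = self.make([(2, 2)])
        assert math.isnan(region_level(s, ("c", 0, 10), "CG",
                                       DMRParams(min_site_coverage=5)))

    def test_min_coverage_one_keeps_single_read(self):
        s = self.make([(0, 1)])
        assert region_level(s, ("c", 0, 10), "CG",
                            DMRParams(min_site_coverage=1)) == 0.0


class TestTestRegion:
    def test_hand_computed_example(self):
        diff, p = run_region_test([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert diff == pytest.approx(0.3)
        assert p == pytest.approx(0.021312, abs=5e-6)

    def test_identical_groups(self):
        diff, p = run_region_test([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert diff == 0.0 and p == 1.0

    def test_equals_pooled_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(5), rng.random(4)
        diff, p = run_region_test(a, b)
        assert p == pytest.approx(st.ttest_ind(a, b).pvalue, rel=1e-9)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            run_region_test([0.1], [0.2, 0.3])


class TestBH:
    def test_hand_step_up(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.37])[0] == pytest.approx(0.37)

    def test_bounds_and_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        adj = adjust_pvalues(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


def make_tested_frame(rows):
    cols = ["comparison", "axis", "chrom", "start", "end", "context",
            "level_a", "level_b", "difference", "p_raw", "n_sites_tested"]
    return pd.DataFrame(rows, columns=cols)


class TestCallDMRs:
    def row(self, diff, p, comp="A_vs_B", context="CG", start=0):
        la = 0.4
        return (comp, INTRAGENERATIONAL, "c", start, start + 1000, context,
                la, la + diff, diff, p, 10)

    def test_filter_rules(self):
        tested = make_tested_frame([
            self.row(+0.25, 0.0001, start=0),     # passes -> hyper
            self.row(+0.15, 0.000001, start=1000),  # fails 20% difference
            self.row(-0.30, 0.9, start=2000),     # fails alpha
        ])
        dmrs = call_dmrs(tested, DMRParams())
        assert len(dmrs) == 1
        assert dmrs["direction"].iloc[0] == "hyper"
        assert dmrs["start"].iloc[0] == 0

    def test_hypo_direction(self):
        tested = make_tested_frame([self.row(-0.30, 0.0001)])
        dmrs = call_dmrs(tested, DMRParams())
        assert dmrs["direction"].iloc[0] == "hypo"

    def test_bh_applied_per_family(self):
        # same raw p in two families must get identical adjusted p
        tested = make_tested_frame(
            [self.row(0.3, 0.01, comp="A_vs_B", start=s)
             for s in range(0, 5000, 1000)]
            + [self.row(0.3, 0.01, comp="A_vs_C", start=0)])
        dmrs = call_dmrs(tested, DMRParams())
        by_comp = dmrs.groupby("comparison")["p_adj"].max()
        assert by_comp["A_vs_B"] == pytest.approx(0.01)
        assert by_comp["A_vs_C"] == pytest.approx(0.01)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        tested = make_tested_frame([self.row(0.5, float(p), start=1000 * i)
                               for i, p in enumerate(rng.random(20))])
        dmrs = call_dmrs(tested, DMRParams(alpha=0.99999))
        assert (dmrs["p_adj"] >= dmrs["p_raw"] - 1e-15).all()

    def test_empty_input(self):
        assert call_dmrs(make_tested_frame([]), DMRParams()).empty


class TestCountMatrix:
    comps = [ComparisonSpec("A_vs_B", "A", "B", INTRAGENERATIONAL),
             ComparisonSpec("A_vs_C", "A", "C", INTERGENERATIONAL)]

    def test_zero_skeleton(self):
        mat = dmr_count_matrix(pd.DataFrame(), self.comps)
        assert len(mat) == 4  # 2 comparisons x 2 directions
        assert (mat[["CG", "CHG", "CHH"]].to_numpy() == 0).all()

    def test_single_dmr_single_cell(self):
        dmrs = call_dmrs(make_tested_frame([
            ("A_vs_B", INTRAGENERATIONAL, "c", 0, 1000, "CG",
             0.3, 0.6, 0.3, 0.001, 5)]), DMRParams())
        mat = dmr_count_matrix(dmrs, self.comps)
        assert mat[["CG", "CHG", "CHH"]].to_numpy().sum() == 1
        hit = mat[(mat["comparison"] == "A_vs_B")
                  & (mat["direction"] == "hyper")]
        assert hit["CG"].iloc[0] == 1

    def test_cell_sum_conservation(self, recovery_tested):
        tested, comparisons = recovery_tested
        dmrs = call_dmrs(tested, DMRParams())
        mat = dmr_count_matrix(dmrs, comparisons)
        assert mat[["CG", "CHG", "CHH"]].to_numpy().sum() == len(dmrs)


class TestSymmetry:
    def test_group_swap_negates_difference_and_swaps_direction(self, small_sim):
        """Swapping the two groups of every comparison negates differences,
        leaves p-values unchanged and exchanges hyper/hypo labels."""
        config, am = small_sim["config"], small_sim["am"]
        comps = [ComparisonSpec("S2g0_vs_S2g30", "S2g0", "S2g30",
                                INTRAGENERATIONAL)]
        swapped = [ComparisonSpec("S2g30_vs_S2g0", "S2g30", "S2g0",
                                  INTRAGENERATIONAL)]
        params = DMRParams()
        fwd = run_all_region_tests(am, comps, config.chrom_lengths, params)
        rev = run_all_region_tests(am, swapped, config.chrom_lengths, params)
        key = ["chrom", "start", "context"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        assert len(merged) == len(fwd) == len(rev) > 0
        assert np.allclose(merged["difference_f"],
                           -merged["difference_r"], atol=1e-12)
        assert np.allclose(merged["p_raw_f"], merged["p_raw_r"], rtol=1e-9)
        df, dr = call_dmrs(fwd, params), call_dmrs(rev, params)
        md = df.merge(dr, on=key, suffixes=("_f", "_r"))
        assert len(md) == len(df) == len(dr)
        assert ((md["direction_f"] == "hyper")
                == (md["direction_r"] == "hypo")).all()
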