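"""Screen profiling tests: ratios, gating, clustering, category calls,
and the screen's test statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from igem import screen
from igem import synthetic as syn
from igem.imaging import WellMeasure
from igem.screen import ScreenError


def _wm(intensity, area=10.0, count=2.0, nuclei=100):
    return WellMeasure("w", nuclei, intensity, area, count)


class TestRatioToControl:
    def test_identical_arms_give_unit_ratios(self):
        reps = [_wm(100.0), _wm(100.0), _wm(100.0)]
        r = screen.ratio_to_control(reps, reps)
        assert np.allclose(r["ratio"], 1.0)
        assert np.allclose(r["se"], 0.0)

    def test_arithmetic_example(self):
        treated = [_wm(90.0), _wm(100.0), _wm(110.0)]
        control = [_wm(200.0), _wm(200.0), _wm(200.0)]
        r = screen.ratio_to_control(treated, control)
        assert r.loc["foci_intensity", "ratio"] == pytest.approx(0.5)
        # SE from treated spread only: sd=10, n=3 -> se/mean = 0.0577
        assert r.loc["foci_intensity", "se"] == pytest.approx(
            0.5 * (10 / np.sqrt(3)) / 100, rel=1e-6
        )

    def test_zero_control_names_parameter(self):
        treated = [_wm(10.0)]
        control = [_wm(0.0)]
        with pytest.raises(ScreenError, match="foci_intensity"):
            screen.ratio_to_control(treated, control)

    def test_scale_equivariance(self):
        treated = [_wm(90.0, 9.0, 1.5), _wm(110.0, 11.0, 2.5)]
        control = [_wm(100.0, 10.0, 2.0)] * 3
        base = screen.ratio_to_control(treated, control)
        scaled = screen.ratio_to_control(
            [_wm(3 * t.foci_intensity_per_nucleus, 3 * t.foci_area_per_nucleus,
                 3 * t.foci_count_per_nucleus, 3 * t.nuclei_count) for t in treated],
            control,
        )
        assert np.allclose(scaled["ratio"], 3 * base["ratio"])


class TestViabilityGate:
    @pytest.mark.parametrize("nuclei_ratio,viable", [(0.69, False), (0.70, True), (1.2, True)])
    def test_boundary_inclusive(self, nuclei_ratio, viable):
        table = pd.DataFrame(
            {"foci_intensity": [1.0], "foci_area": [1.0], "foci_count": [1.1],
             "nuclei_count": [nuclei_ratio]}, index=["x"]
        )
        assert screen.viability_gate(table)["viable"].iloc[0] == viable

    def test_empty_table(self):
        table = pd.DataFrame(columns=screen.RATIO_COLUMNS)
        assert len(screen.viability_gate(table)) == 0


class TestClustering:
    def test_three_distinct_profiles_are_singletons(self):
        table = pd.DataFrame(
            [(0.6, 0.6, 0.6, 1.2), (1.4, 1.4, 1.4, 0.8), (1.0, 1.0, 1.01, 0.99)],
            columns=screen.RATIO_COLUMNS, index=list("abc"),
        )
        _, clusters = screen.cluster_chemicals(table, k=3)
        assert clusters.nunique() == 3

    def test_constant_profile_is_hard_error(self):
        table = pd.DataFrame(
            [(0.6, 0.6, 0.6, 1.2), (1.4, 1.4, 1.4, 0.8), (1.0, 1.0, 1.0, 1.0)],
            columns=screen.RATIO_COLUMNS, index=list("abc"),
        )
        with pytest.raises(ScreenError, match="c"):
            screen.cluster_chemicals(table, k=3)

    def test_partition_matches_generated_categories(self, small_cfg):
        table, truth = syn.gen_screen_table(small_cfg)
        _, clusters = screen.cluster_chemicals(table, k=3)
        ari = adjusted_rand_score(truth.categories.loc[clusters.index], clusters)
        assert ari == pytest.approx(1.0)

    def test_row_permutation_invariance(self, small_cfg):
        table, _ = syn.gen_screen_table(small_cfg)
        _, base = screen.cluster_chemicals(table, k=3)
        shuffled = table.sample(frac=1.0, random_state=5)
        _, perm = screen.cluster_chemicals(shuffled, k=3)
        assert adjusted_rand_score(base.loc[table.index], perm.loc[table.index]) == 1.0


class TestCategories:
    def test_cluster_mean_profiles_map_to_expected_labels(self):
        table = pd.DataFrame(
            [(1.37, 1.35, 1.34, 0.9), (0.56, 0.56, 0.63, 1.1), (1.0, 1.0, 1.0, 1.0)],
            columns=screen.RATIO_COLUMNS, index=["hyper", "hypo", "none"],
        )
        clusters = pd.Series([1, 2, 3], index=table.index)
        calls = {c.chemical: c.category for c in screen.assign_categories(clusters, table)}
        assert calls == {"hyper": "B", "hypo": "A", "none": "C"}

    def test_delta_band_rule_without_three_clusters(self):
        table = pd.DataFrame(
            [(1.02, 1.03, 1.01, 1.0), (0.5, 0.5, 0.5, 1.2)],
            columns=screen.RATIO_COLUMNS, index=["mild", "strong"],
        )
        clusters = pd.Series([1, 2], index=table.index)
        calls = {c.chemical: c.category for c in screen.assign_categories(clusters, table)}
        assert calls == {"mild": "C", "strong": "A"}

    def test_full_screen_recovery(self, small_cfg):
        table, truth = syn.gen_screen_table(small_cfg)
        calls = screen.categorize_screen(table)
        assert (calls["category"] == truth.categories.loc[calls.index]).all()


class TestNewick:
    def test_roundtrip_preserves_leaves(self, small_cfg):
        import dendropy

        table, _ = syn.gen_screen_table(small_cfg)
        linkage, _ = screen.cluster_chemicals(table.head(12), k=3)
        text = screen.linkage_to_newick(linkage, list(table.head(12).index))
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(table.head(12).index)


class TestDoseResponse:
    def test_identical_groups_are_null(self):
        groups = {"ctrl": np.ones(5), "d1": np.ones(5), "d2": np.ones(5)}
        omnibus, pairwise = screen.dose_response_test(groups, "ctrl")
        assert omnibus.statistic == 0.0 and omnibus.p_value == pytest.approx(1.0)
        assert all(p.p_value > 0.9 for p in pairwise)

    def test_strong_shift_detected(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 1, 10)
        omnibus, pairwise = screen.dose_response_test({"ctrl": a, "dose": b}, "ctrl")
        # closed-form one-way F for two groups
        grand = np.concatenate([a, b]).mean()
        ssb = 10 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_expected = (ssb / 1) / (ssw / 18)
        assert omnibus.statistic == pytest.approx(f_expected, rel=1e-9)
        assert omnibus.p_value < 1e-3
        # Tukey p against the studentized-range law directly
        q = abs(a.mean() - b.mean()) / np.sqrt(ssw / 18 / 10)
        p_expected = stats.studentized_range.sf(q, 2, 18)
        assert pairwise[0].p_value == pytest.approx(p_expected, rel=1e-6)
        assert pairwise[0].p_value < 1e-3

    def test_missing_control_label(self):
        with pytest.raises(ScreenError):
            screen.dose_response_test({"a": np.ones(3), "b": np.ones(3)}, "ctrl")


class TestSteelDwass:
    def test_identical_groups_not_significant(self):
        groups = [np.ones(5), np.ones(5), np.ones(5)]
        assert all(r.p_value >= 0.99 for r in screen.steel_dwass(groups))

    def test_separated_groups_all_significant(self):
        groups = [np.arange(1, 9.0), np.arange(11, 19.0), np.arange(21, 29.0)]
        assert all(r.p_value < 0.01 for r in screen.steel_dwass(groups))

    def test_k2_asymptotic_matches_tie_corrected_wilcoxon(self):
        x = np.array([1.2, 2.3, 2.3, 4.1, 5.0, 6.1, 7.7, 3.3])
        y = np.array([2.3, 3.3, 4.1, 7.2, 8.0, 9.9, 1.1, 6.1])
        r = screen.steel_dwass([x, y], method="asymptotic")[0]
        mw = stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
        assert r.p_value == pytest.approx(mw.pvalue, abs=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ScreenError):
            screen.steel_dwass([np.array([1.0]), np.array([1.0, 2.0])])

    def test_permutation_reference_is_deterministic(self):
        groups = [np.arange(8.0), np.arange(8.0) + 1.5, np.arange(8.0) + 3]
        p1 = [r.p_value for r in screen.steel_dwass(groups, seed=4)]
        p2 = [r.p_value for r in screen.steel_dwass(groups, seed=4)]
        assert p1 == p2
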