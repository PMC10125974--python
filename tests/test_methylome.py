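"""Methylome analytics tests: log2 summaries, DiffScore, region
distributions, gene panels, RRBS processing, embedding, expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igem import methylome as me
from igem import synthetic as syn
from igem.methylome import MethylomeError


@pytest.fixture(scope="module")
def beta_world(small_cfg):
    beta, ann, truth = syn.gen_beta_matrix(small_cfg)
    return beta, ann, truth


class TestBetaLog2:
    def test_identity_is_zero(self):
        b = pd.Series([0.1, 0.5, 0.9], index=list("abc"))
        ratios, mean = me.beta_log2_summary(b, b)
        assert (ratios == 0).all() and mean == 0.0

    def test_doubling_is_one(self):
        t = pd.Series([0.8], index=["x"])
        c = pd.Series([0.4], index=["x"])
        ratios, _ = me.beta_log2_summary(t, c)
        assert ratios.iloc[0] == pytest.approx(1.0)

    def test_floor_prevents_infinities(self):
        t = pd.Series([0.0], index=["x"])
        c = pd.Series([0.5], index=["x"])
        ratios, _ = me.beta_log2_summary(t, c, floor=1e-3)
        assert np.isfinite(ratios.iloc[0])

    def test_island_effect_ordering(self, beta_world):
        beta, ann, _ = beta_world
        ratios, mean = me.beta_log2_summary(beta["etoposide"], beta["control"])
        island = ratios[(ann["cpg_context"] == "island").to_numpy()].mean()
        open_sea = ratios[(ann["cpg_context"] == "open_sea").to_numpy()].mean()
        assert mean > 0 and island > open_sea


class TestDiffScore:
    def test_score_at_p05(self):
        score = me.diff_score(0.6, 0.4, p=0.05)
        assert score == pytest.approx(13.0103, abs=1e-3)
        assert int(score) == 13

    def test_threshold_is_strict(self):
        df = me.diff_score(pd.Series([0.6]), pd.Series([0.4]), p=pd.Series([0.05]))
        assert len(me.call_hypermethylated(df)) == 0
        df2 = me.diff_score(pd.Series([0.6]), pd.Series([0.4]), p=pd.Series([0.04]))
        assert len(me.call_hypermethylated(df2)) == 1

    @pytest.mark.parametrize("p,expected", [(1.0, 0.0), (0.01, 20.0)])
    def test_log_scale(self, p, expected):
        assert me.diff_score(0.7, 0.2, p=p) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        bt=st.floats(0.0, 1.0, allow_nan=False),
        bc=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_antisymmetry(self, bt, bc):
        assert me.diff_score(bt, bc) == pytest.approx(-me.diff_score(bc, bt), abs=1e-9)

    def test_sign_matches_delta(self):
        assert me.diff_score(0.2, 0.6) < 0 < me.diff_score(0.6, 0.2)


class TestRegionDistribution:
    def test_all_island_calls(self, beta_world):
        beta, ann, _ = beta_world
        island_probes = ann.index[ann["cpg_context"] == "island"][:50]
        called = pd.DataFrame(index=island_probes)
        dist = me.region_distribution(called, ann)
        assert dist["cpg_context"].loc["island", "proportion"] == 1.0

    def test_empty_calls_flagged(self, beta_world):
        _, ann, _ = beta_world
        dist = me.region_distribution(pd.DataFrame(index=pd.Index([])), ann)
        assert len(dist["cpg_context"]) == 0

    def test_proportions_sum_to_one(self, beta_world):
        beta, ann, _ = beta_world
        scores = me.diff_score(beta["etoposide"], beta["control"])
        called = me.call_hypermethylated(scores)
        dist = me.region_distribution(called, ann)
        for axis in ("refgene_group", "cpg_context"):
            assert dist[axis]["proportion"].sum() == pytest.approx(1.0)


class TestGenePanel:
    def test_gene_without_probes_is_flagged(self, beta_world):
        beta, ann, _ = beta_world
        out = me.gene_panel_methylation(beta, ann, ["NOSUCHGENE"], "etoposide")
        assert out.loc["NOSUCHGENE", "n_sites"] == 0
        assert np.isnan(out.loc["NOSUCHGENE", "mean_log2_ratio"])

    def test_unchanged_gene_is_zero(self, beta_world):
        beta, ann, truth = beta_world
        # a panel gene never planted for theophylline
        out = me.gene_panel_methylation(beta, ann, ["JAG1"], "theophylline")
        assert out.loc["JAG1", "mean_log2_ratio"] == 0.0

    def test_planted_hyper_sets_recovered(self, beta_world):
        beta, ann, truth = beta_world
        panel = list(truth.panel.panel)
        for chem, expected in (
            ("etoposide", set(truth.panel.hyper_etoposide)),
            ("propyl_gallate", set(truth.panel.hyper_propyl_gallate)),
        ):
            pm = me.gene_panel_methylation(beta, ann, panel, chem)
            positive = set(pm.index[pm["mean_log2_ratio"] > 0])
            assert positive == expected


class TestCommonHyperGenes:
    def test_generator_plants_exactly_twelve(self, beta_world):
        beta, ann, truth = beta_world
        calls = {
            c: me.call_hypermethylated(me.diff_score(beta[c], beta["control"]))
            for c in ("etoposide", "propyl_gallate")
        }
        common = me.common_hyper_genes(
            calls["etoposide"], calls["propyl_gallate"], beta, ann,
            "etoposide", "propyl_gallate",
        )
        assert common == set(truth.common_hyper_genes)

    def test_disjoint_sets_empty(self, beta_world):
        beta, ann, _ = beta_world
        empty = pd.DataFrame(index=pd.Index([]))
        some = pd.DataFrame(index=ann.index[:10])
        assert me.common_hyper_genes(empty, some, beta, ann, "etoposide", "propyl_gallate") == set()


class TestRrbsFilter:
    def test_coverage_boundaries(self):
        cov = [9, 10] + [30] * 40  # wide body so the ceiling sits above 30
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(len(cov)) + 1, "strand": "+",
             "coverage": cov, "n_meth": 1}
        )
        kept, info = me.rrbs_filter(calls)
        assert 9 not in kept["coverage"].to_numpy()
        assert 10 in kept["coverage"].to_numpy()
        assert info["low_coverage_removed"] == 1
        assert info["high_coverage_removed"] == 0

    def test_percentile_rule_removes_spike(self, rng):
        cov = np.full(10_000, 30)
        cov[1234] = 300
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(10_000) + 1, "strand": "+",
             "coverage": cov, "n_meth": 0}
        )
        kept, info = me.rrbs_filter(calls)
        assert info["high_coverage_removed"] == 1
        assert 300 not in kept["coverage"].to_numpy()

    def test_band_is_never_removed(self, small_cfg):
        tables, _, _ = syn.gen_rrbs_calls(small_cfg)
        calls = tables["control"]
        kept, info = me.rrbs_filter(calls)
        hi = info["coverage_ceiling"]
        in_band = calls[(calls["coverage"] >= 10) & (calls["coverage"] <= hi)]
        assert len(kept) == len(in_band)


class TestRrbsNormalize:
    def test_identical_samples_unchanged(self, small_cfg):
        tables, _, _ = syn.gen_rrbs_calls(small_cfg)
        t = tables["control"]
        out = me.rrbs_normalize_coverage({"a": t, "b": t.copy()})
        pd.testing.assert_frame_equal(out["a"], t)

    def test_double_coverage_rescaled_to_common_median(self):
        t = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(100) + 1, "strand": "+",
             "coverage": np.full(100, 20), "n_meth": np.full(100, 10)}
        )
        t2 = t.assign(coverage=t["coverage"] * 2, n_meth=t["n_meth"] * 2)
        out = me.rrbs_normalize_coverage({"a": t, "b": t2})
        assert np.median(out["a"]["coverage"]) == np.median(out["b"]["coverage"])
        assert (out["b"]["n_meth"] / out["b"]["coverage"]).iloc[0] == pytest.approx(0.5)

    def test_fractions_preserved_within_rounding(self, small_cfg):
        tables, _, _ = syn.gen_rrbs_calls(small_cfg)
        filtered = {s: me.rrbs_filter(t)[0] for s, t in tables.items()}
        out = me.rrbs_normalize_coverage(filtered)
        for s in filtered:
            before = filtered[s]["n_meth"] / filtered[s]["coverage"]
            after = out[s]["n_meth"] / out[s]["coverage"]
            drift = (before - after).abs()
            # exact per-site rounding bound, and negligible in aggregate
            assert (drift <= 0.5 / out[s]["coverage"] + 1e-12).all()
            assert drift.mean() < 0.01


class TestRrbsTile:
    def test_single_site_window(self):
        calls = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1500], "strand": ["+"],
             "coverage": [20], "n_meth": [15]}
        )
        tiles = me.rrbs_tile(calls)
        row = tiles.iloc[0]
        assert (row["start"], row["coverage"], row["n_meth"]) == (1001, 20, 15)
        assert row["fraction"] == pytest.approx(0.75)

    def test_empty_input(self):
        assert len(me.rrbs_tile(pd.DataFrame(columns=["chrom", "pos", "strand", "coverage", "n_meth"]))) == 0

    def test_two_sites_pool_counts(self):
        calls = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [1100, 1900], "strand": ["+", "-"],
             "coverage": [20, 40], "n_meth": [10, 30]}
        )
        tiles = me.rrbs_tile(calls)
        assert len(tiles) == 1
        assert tiles.iloc[0]["fraction"] == pytest.approx(40 / 60)

    def test_count_conservation(self, small_cfg):
        tables, _, _ = syn.gen_rrbs_calls(small_cfg)
        kept, _ = me.rrbs_filter(tables["control"])
        tiles = me.rrbs_tile(kept)
        assert tiles["coverage"].sum() == kept["coverage"].sum()
        assert tiles["n_meth"].sum() == kept["n_meth"].sum()


class TestRrbsGeneMethylation:
    def test_confirmed_genes_recovered(self, small_cfg):
        tables, ann, truth = syn.gen_rrbs_calls(small_cfg)
        filtered = {s: me.rrbs_filter(t)[0] for s, t in tables.items()}
        norm = me.rrbs_normalize_coverage(filtered)
        genes = [g for g in sorted(set(ann["gene"])) if g]
        gm = {
            c: me.rrbs_gene_methylation(norm[c], norm["control"], ann, genes)
            for c in ("etoposide", "propyl_gallate")
        }
        confirmed = {
            g for g in genes
            if gm["etoposide"].loc[g, "mean_log2_ratio"] > 0.30
            and gm["propyl_gallate"].loc[g, "mean_log2_ratio"] > 0.30
        }
        assert confirmed == set(truth.confirmed_genes)


class TestTsne:
    def test_duplicates_embed_closest(self, beta_world):
        beta, _, _ = beta_world
        fc = np.log2(beta.drop(columns="control").clip(lower=1e-3).div(
            beta["control"].clip(lower=1e-3), axis=0))
        emb = me.tsne_embed(fc.T, seed=0)
        d = lambda a, b: np.hypot(*(emb.loc[a] - emb.loc[b]))
        # theophylline and bisphenol_a have identical (null) profiles
        dup = d("theophylline", "bisphenol_a")
        others = [d(a, b) for a in emb.index for b in emb.index
                  if a < b and {a, b} != {"theophylline", "bisphenol_a"}]
        assert dup <= min(others)

    def test_seed_determinism(self, beta_world):
        beta, _, _ = beta_world
        fc = beta.drop(columns="control").T
        pd.testing.assert_frame_equal(me.tsne_embed(fc, seed=3), me.tsne_embed(fc, seed=3))

    def test_hyper_agents_form_a_group(self, beta_world):
        from sklearn.metrics import silhouette_score

        beta, _, _ = beta_world
        fc = np.log2(beta.drop(columns="control").clip(lower=1e-3).div(
            beta["control"].clip(lower=1e-3), axis=0))
        emb = me.tsne_embed(fc.T, seed=0)
        labels = [1 if s in ("biotin", "etoposide", "propyl_gallate") else 0
                  for s in emb.index]
        assert silhouette_score(emb.to_numpy(), labels) > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(MethylomeError):
            me.tsne_embed(pd.DataFrame(np.eye(2)), seed=0)


class TestExpression:
    def test_identity_and_zero_control_handling(self, small_cfg):
        genes = [f"g{i}" for i in range(5)]
        expr = pd.DataFrame(
            {"control": [10.0, 20, 0.0, 5, 8], "t1": [10.0, 20, 4.0, 5, 8],
             "t2": [10.0, 20, 4.0, 5, 8]}, index=genes,
        )
        res = me.expression_analysis(expr, common_pair=("t1", "t2"))
        assert res.excluded_genes == ["g2"]
        assert np.allclose(res.fold_change, 1.0)
        assert res.common_down == set()

    def test_planted_common_down_recovered(self, small_cfg):
        _, _, btruth = syn.gen_beta_matrix(small_cfg)
        expr, etruth = syn.gen_expression(small_cfg, btruth)
        res = me.expression_analysis(expr)
        assert res.common_down == set(etruth.common_down)
        assert len(res.common_down) == 28

    def test_funnel_counts(self, small_cfg, beta_world):
        beta, ann, btruth = beta_world
        expr, _ = syn.gen_expression(small_cfg, btruth)
        res = me.expression_analysis(expr)
        pm = {
            c: me.gene_panel_methylation(beta, ann, list(btruth.panel.panel), c)
            for c in ("etoposide", "propyl_gallate")
        }
        funnel = me.methylation_expression_funnel(
            res.common_down, pm["etoposide"], pm["propyl_gallate"]
        )
        assert funnel == (28, 16, 9)

    def test_funnel_degenerate_inputs(self, beta_world):
        beta, ann, btruth = beta_world
        pm = me.gene_panel_methylation(beta, ann, list(btruth.panel.panel), "theophylline")
        # no methylation change anywhere -> nothing called hypermethylated
        assert me.methylation_expression_funnel({"JAG1", "RB1"}, pm, pm) == (2, 0, 0)
        assert me.methylation_expression_funnel(set(), pm, pm) == (0, 0, 0)
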