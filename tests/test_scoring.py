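"""Scoring chain: ANOVA filter, shrinkage pcor, null p-values, h and MPH/BPH."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from heteronet import scoring, synthetic
from heteronet.scoring import (
    bph_scores,
    collapse_gene_models,
    compute_h_table,
    estimate_shrinkage_pcor,
    fdr_adjust,
    filter_genes_anova,
    mph_scores,
    pcor_pvalues,
    rank_genes,
)
from heteronet.synthetic import GENOTYPES, ExpressionPanel


def _make_panels(values_by_genotype, time, repl, gene_ids):
    return {
        g: ExpressionPanel(genotype=g, values=np.asarray(v, dtype=float),
                           gene_ids=tuple(gene_ids), time=np.asarray(time),
                           replicate=np.asarray(repl))
        for g, v in values_by_genotype.items()
    }


@pytest.fixture(scope="module")
def panels():
    rng = np.random.default_rng(5)
    T, R = 5, 3
    time = np.repeat(np.arange(1, T + 1), R)
    repl = np.tile(np.arange(1, R + 1), T)
    genes = ["constant", "time_signal", "noise", "interaction"]
    vals = {}
    for g in GENOTYPES:
        cols = [
            np.zeros(T * R),                      # constant everywhere
            time.astype(float),                   # exact time signal, no noise
            rng.standard_normal(T * R),           # pure noise
            time * (1.0 if g.startswith("H") else -1.0)
            + 0.1 * rng.standard_normal(T * R),   # genotype x time interaction
        ]
        vals[g] = np.column_stack(cols)
    return _make_panels(vals, time, repl, genes)


class TestAnovaFilter:
    def test_filter_keeps_signal_drops_flat(self, panels):
        kept = filter_genes_anova(panels, alpha=0.3)
        assert "time_signal" in kept
        assert "interaction" in kept
        assert "constant" not in kept

    def test_matches_statsmodels_anova(self, panels):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        # recompute the per-gene two-way ANOVA p-values with statsmodels
        T = 5
        rows = []
        for g in GENOTYPES:
            panel = panels[g]
            for s in range(panel.n_samples):
                rows.append({"genotype": g, "time": panel.time[s],
                             "noise": panel.values[s, 2],
                             "interaction": panel.values[s, 3]})
        df = pd.DataFrame(rows)
        ours_time, ours_int = {}, {}
        for gene_col in ("noise", "interaction"):
            fit = smf.ols(f"{gene_col} ~ C(genotype) * C(time)", data=df).fit()
            tbl = sm.stats.anova_lm(fit, typ=2)
            ours_time[gene_col] = tbl.loc["C(time)", "PR(>F)"]
            ours_int[gene_col] = tbl.loc["C(genotype):C(time)", "PR(>F)"]

        # reach into the vectorized implementation via a 2-gene filter at alpha=1
        sub = {
            g: ExpressionPanel(genotype=g, values=panels[g].values[:, 2:4],
                               gene_ids=("noise", "interaction"),
                               time=panels[g].time, replicate=panels[g].replicate)
            for g in GENOTYPES
        }
        # alpha=1 keeps everything; we validate the p-values through BH on m=2
        kept = filter_genes_anova(sub, alpha=1.0)
        assert kept == ["noise", "interaction"]
        p_time, p_int = scoring.anova_effect_pvalues(sub)
        np.testing.assert_allclose(p_time[0], ours_time["noise"], rtol=1e-8)
        np.testing.assert_allclose(p_time[1], ours_time["interaction"], rtol=1e-8)
        np.testing.assert_allclose(p_int[0], ours_int["noise"], rtol=1e-8)
        np.testing.assert_allclose(p_int[1], ours_int["interaction"], rtol=1e-8)

    def test_degenerate_designs_rejected(self, panels):
        rng = np.random.default_rng(0)
        single_time = _make_panels(
            {g: rng.standard_normal((4, 2)) for g in GENOTYPES},
            time=[1, 1, 1, 1], repl=[1, 2, 3, 4], gene_ids=["a", "b"],
        )
        with pytest.raises(ValueError, match="time point"):
            filter_genes_anova(single_time)
        single_rep = {
            g: ExpressionPanel(genotype=g, values=p.values[p.replicate == 1],
                               gene_ids=p.gene_ids,
                               time=p.time[p.replicate == 1],
                               replicate=p.replicate[p.replicate == 1])
            for g, p in panels.items()
        }
        with pytest.raises(ValueError, match="replicate"):
            filter_genes_anova(single_rep)


class TestShrinkagePcor:
    def test_two_genes_equals_shrunken_correlation(self, rng):
        x = rng.standard_normal((40, 2))
        x[:, 1] = 0.6 * x[:, 0] + 0.8 * x[:, 1]
        pcor, lam = estimate_shrinkage_pcor(x)
        r = np.corrcoef(x.T)[0, 1]
        np.testing.assert_allclose(pcor[0, 1], (1 - lam) * r, atol=1e-12)

    def test_chain_conditional_independence(self, rng):
        # X -> Y -> Z: pcor(X,Z | Y) ~ 0 while the chain links are strong
        n = 5000
        x = rng.standard_normal(n)
        y = 0.8 * x + 0.6 * rng.standard_normal(n)
        z = 0.8 * y + 0.6 * rng.standard_normal(n)
        pcor, _ = estimate_shrinkage_pcor(np.column_stack([x, y, z]))
        assert abs(pcor[0, 2]) < 0.05
        assert abs(pcor[0, 1]) > 0.2 and abs(pcor[1, 2]) > 0.2

    def test_pure_noise_shrinks_to_identity(self, rng):
        x = rng.standard_normal((10, 200))
        pcor, lam = estimate_shrinkage_pcor(x)
        assert lam > 0.7
        off = pcor[np.triu_indices(200, k=1)]
        assert np.abs(off).max() < 0.1

    def test_zero_variance_gene_named(self, rng):
        x = rng.standard_normal((20, 5))
        x[:, 3] = 2.5
        with pytest.raises(ValueError, match="3"):
            estimate_shrinkage_pcor(x)

    def test_sign_pattern_recovered_at_large_n(self, catalog_small):
        ens = synthetic.plant_networks(catalog_small, 30, base_edges_per_gene=2.0,
                                       n_heterosis_genes=5, extra_hybrid_edges=3,
                                       seed=8)
        panels = synthetic.simulate_expression(ens, n_timepoints=1000,
                                               n_replicates=4, seed=8,
                                               time_effect_sd=0.0)
        pcor, _ = estimate_shrinkage_pcor(panels["H12"].values)
        true = ens.true_partial_correlations("H12")
        iu = np.triu_indices(30, k=1)
        strong = np.abs(true[iu]) > 0.15
        assert strong.sum() >= 10
        agree = np.sign(pcor[iu][strong]) == np.sign(true[iu][strong])
        assert agree.mean() >= 0.95


class TestPcorPvalues:
    def test_boundaries(self):
        pcor = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, -1.0], [1.0, -1.0, 1.0]])
        pvals, _ = pcor_pvalues(pcor, fallback_kappa=10.0)
        assert pvals[0, 1] == pytest.approx(1.0)
        assert pvals[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert pvals[1, 2] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(np.diag(pvals)).all()

    def test_null_pvalues_uniform(self, rng):
        x = rng.standard_normal((50, 60))
        pcor, _ = estimate_shrinkage_pcor(x)
        pvals, kappa = pcor_pvalues(pcor)
        vals = pvals[np.triu_indices(60, k=1)]
        assert len(vals) >= 1000
        assert stats.kstest(vals, "uniform").pvalue > 0.01
        assert kappa > 3


class TestFdrAdjust:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-15)

    def test_fixed_points(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
        np.testing.assert_allclose(fdr_adjust([0.7]), [0.7])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(25):
            p = rng.random(rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, np.nan])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_properties(self, pvals):
        adj = fdr_adjust(pvals)
        p = np.asarray(pvals)
        assert ((adj >= p - 1e-15) & (adj <= 1.0 + 1e-15)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()  # order preserving


class TestHTableAndScores:
    def test_hand_arithmetic(self):
        p = np.array([[np.nan, 0.2, 0.6],
                      [0.2, np.nan, 1.0],
                      [0.6, 1.0, np.nan]])
        h = compute_h_table({g: p for g in GENOTYPES}, ["a", "b", "c"])
        assert h.loc["a", "P1"] == pytest.approx(np.mean([0.8, 0.4]))

    def test_boundary_h_values(self):
        ids = ["a", "b", "c"]
        zeros = np.zeros((3, 3))
        ones = np.ones((3, 3))
        h0 = compute_h_table({g: ones for g in GENOTYPES}, ids)
        h1 = compute_h_table({g: zeros for g in GENOTYPES}, ids)
        assert (h0.to_numpy() == 0.0).all()
        assert (h1.to_numpy() == 1.0).all()

    def test_mph_bph_arithmetic(self):
        h = pd.DataFrame({"P1": [0.5], "P2": [0.7], "H12": [0.9], "H21": [0.6]},
                         index=["g"])
        assert mph_scores(h, "H12")["g"] == pytest.approx(0.3)
        assert bph_scores(h, "H12")["g"] == pytest.approx(0.2)
        assert mph_scores(h, "H21")["g"] == pytest.approx(0.0)

    def test_equal_parents_make_bph_equal_mph(self):
        h = pd.DataFrame({"P1": [0.4, 0.1], "P2": [0.4, 0.1],
                          "H12": [0.6, 0.05], "H21": [0.2, 0.3]},
                         index=["g1", "g2"])
        pd.testing.assert_series_equal(
            mph_scores(h, "H12"), bph_scores(h, "H12"), check_names=False
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(*[st.floats(0, 1)] * 4), min_size=1, max_size=20))
    def test_score_ranges_and_ordering(self, rows):
        h = pd.DataFrame(rows, columns=list(GENOTYPES),
                         index=[f"g{i}" for i in range(len(rows))])
        for hyb in ("H12", "H21"):
            mph = mph_scores(h, hyb)
            bph = bph_scores(h, hyb)
            assert ((mph >= -1) & (mph <= 1)).all()
            assert ((bph >= -1) & (bph <= 1)).all()
            assert (bph <= mph + 1e-15).all()

    def test_missing_genotype_rejected(self):
        h = pd.DataFrame({"P1": [0.5], "H12": [0.9]})
        with pytest.raises(ValueError):
            mph_scores(h, "H12")

    def test_ranking_deterministic_ties(self):
        s = pd.Series({"g2": 0.5, "g1": 0.5, "g3": 0.9})
        assert rank_genes(s) == ["g3", "g1", "g2"]


class TestCollapseGeneModels:
    def test_averaging_and_drops(self):
        scores = {"m1": 0.2, "m2": 0.4, "m3": 0.7, "orphan": 0.9}
        mapping = {"m1": "gA", "m2": "gA", "m3": "gB"}
        collapsed, dropped = collapse_gene_models(scores, mapping)
        assert collapsed == {"gA": pytest.approx(0.3), "gB": 0.7}
        assert dropped == 1

    def test_identity_map(self):
        scores = {"a": 0.1, "b": 0.2}
        collapsed, dropped = collapse_gene_models(scores, {"a": "a", "b": "b"})
        assert collapsed == scores and dropped == 0


class TestPlantedSignal:
    def test_planted_genes_rank_high(self, scored_small):
        """Planted heterosis genes concentrate at the top of the MPH ranking."""
        ranked = scored_small.ranking("H12", "mph")
        rank_of = {g: i for i, g in enumerate(ranked)}
        planted = [rank_of[g] for g in scored_small.ensemble.heterosis_genes
                   if g in rank_of]
        assert np.mean(planted) < 0.35 * len(ranked)

    def test_null_scores_centered_at_zero(self):
        """Without planted genes the per-seed mean MPH is centred at 0.

        Per-gene MPH values are strongly correlated within a seed (they share
        the estimated pair-significance tables), so the centring is judged on
        the distribution of per-seed means across 20 independent simulations.
        """
        from heteronet.study import simulate_study

        means = {"H12": [], "H21": []}
        for s in range(20):
            study = simulate_study(
                91_000 + 7 * s, n_genes=400, n_analyzed=150,
                n_heterosis_genes=0, n_qtl_regions=10, apply_filter=False)
            for hyb in means:
                means[hyb].append(study.scored.scores[f"mph_{hyb}"].mean())
        for hyb, vals in means.items():
            vals = np.asarray(vals)
            t = vals.mean() / (vals.std(ddof=1) / np.sqrt(len(vals)))
            assert abs(t) < 3.0, f"{hyb}: t={t:.2f}"
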