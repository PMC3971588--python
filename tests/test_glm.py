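"""Per-pair NB GLM: fitting, contrasts, categories, complementary, ANOVA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from paleodup.expression import upper_quartile
from paleodup.glm import (
    CATEGORY_OF,
    assign_categories,
    contrast_tests,
    detect_complementary,
    fit_pair_glm,
    glm_pairwise,
    pooled_anova,
)
from paleodup.synthetic import SimulationDesign, simulate_counts


def tidy(counts1, counts2, tissues=("a", "b", "c"), offset=None):
    n = len(counts1) // len(tissues)
    rows = []
    for i, y in enumerate(counts1):
        rows.append({"count": y, "gene": "g1", "tissue": tissues[i // n]})
    for i, y in enumerate(counts2):
        rows.append({"count": y, "gene": "g2", "tissue": tissues[i // n]})
    df = pd.DataFrame(rows)
    if offset is not None:
        df["offset"] = np.concatenate([offset, offset])
    return df


class TestFitPairGlm:
    def test_symmetric_input_zero_gene_and_interaction(self):
        data = tidy([10, 10, 10, 10, 10, 10], [10, 10, 10, 10, 10, 10], ("a", "b"))
        fit = fit_pair_glm(data, dispersion=0.05)
        assert abs(fit.params["gene"]) < 1e-6
        assert abs(fit.params["gene:tissue[b]"]) < 1e-6
        tests = contrast_tests(fit)
        assert tests["p_G"] > 0.99
        assert tests["p_GxT"] > 0.99

    def test_offset_identity_shifts_intercept_only(self):
        data0 = tidy([12, 9, 11, 30, 28, 33], [11, 13, 9, 31, 30, 29], ("a", "b"))
        c = 1.7
        data1 = data0.copy()
        data1["offset"] = c
        f0 = fit_pair_glm(data0, dispersion=0.05)
        f1 = fit_pair_glm(data1, dispersion=0.05)
        assert f1.params["const"] == pytest.approx(f0.params["const"] - c, abs=1e-6)
        for name in f0.params.index[1:]:
            assert f1.params[name] == pytest.approx(f0.params[name], abs=1e-6)

    def test_non_integer_counts_rejected(self):
        data = tidy([1.5, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6], ("a", "b"))
        with pytest.raises(ValueError, match="integer"):
            fit_pair_glm(data)

    def test_gene_effect_recovery_large_reps(self):
        """Planted ln(2) gene effect recovered within 0.1 at n_reps=50."""
        design = SimulationDesign(
            n_pairs=6, n_reps=50, scenario_mix={"G_only": 1.0},
            effect_log2fc=1.0, seed=4,
        )
        cm, samples, truth = simulate_counts(design)
        res = glm_pairwise(cm, samples, truth, dispersion="mle")
        # model codes gene2 relative to gene1: coefficient -> -ln 2; the
        # per-tissue proportion implies the averaged gene effect
        for rec in res.itertuples():
            props = [getattr(rec, f"prop_gene1_{t}") for t in ("leaf", "petal", "seed")]
            est = np.mean([np.log(p / (1 - p)) for p in props])
            assert est == pytest.approx(np.log(2), abs=0.1)

    def test_separation_flagged_not_fatal(self):
        data = tidy([0, 0, 0, 30, 28, 33], [25, 30, 21, 31, 30, 29], ("a", "b"))
        fit = fit_pair_glm(data)
        assert "near_boundary" in fit.flags

    def test_poisson_limit_matches_irls_oracle(self):
        """Fixed phi=0 fit equals a hand-rolled Poisson IRLS on a 2x2 toy."""
        y1, y2 = [7, 9, 12, 30, 26, 35], [14, 11, 9, 60, 52, 64]
        data = tidy(y1, y2, ("a", "b"))
        fit = fit_pair_glm(data, dispersion=0.0)

        # independent IRLS oracle
        y = np.array(y1 + y2, dtype=float)
        g = np.array([0] * 6 + [1] * 6)
        t = np.array(([0] * 3 + [1] * 3) * 2)
        X = np.column_stack([np.ones(12), g, t, g * t]).astype(float)
        beta = np.array([np.log(y.mean()), 0.0, 0.0, 0.0])
        for _ in range(100):
            eta = X @ beta
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            W = mu
            beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
            if np.max(np.abs(beta_new - beta)) < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        cov = np.linalg.inv(X.T @ (np.exp(X @ beta)[:, None] * X))
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-6)
        np.testing.assert_allclose(fit.cov.to_numpy(), cov, atol=1e-6)


class TestCategories:
    def test_mapping_is_the_exhaustive_significance_lattice(self):
        df = pd.DataFrame(
            [
                {"q_G": 0.9, "q_T": 0.9, "q_GxT": 0.9},   # i
                {"q_G": 0.01, "q_T": 0.9, "q_GxT": 0.9},  # ii
                {"q_G": 0.9, "q_T": 0.01, "q_GxT": 0.9},  # iii
                {"q_G": 0.9, "q_T": 0.9, "q_GxT": 0.01},  # iv
                {"q_G": 0.01, "q_T": 0.01, "q_GxT": 0.9},  # v
                {"q_G": 0.01, "q_T": 0.9, "q_GxT": 0.01},  # vi
                {"q_G": 0.9, "q_T": 0.01, "q_GxT": 0.01},  # vii
                {"q_G": 0.01, "q_T": 0.01, "q_GxT": 0.01},  # viii
            ]
        )
        cats = assign_categories(df, fdr=0.05)
        assert list(cats) == ["i", "ii", "iii", "iv", "v", "vi", "vii", "viii"]
        assert len(CATEGORY_OF) == 8

    def test_boundary_q_equal_fdr_is_significant(self):
        df = pd.DataFrame([{"q_G": 0.05, "q_T": 0.05, "q_GxT": 0.05}])
        assert assign_categories(df, fdr=0.05).iloc[0] == "viii"

    def test_missing_q_withholds_category(self):
        df = pd.DataFrame([{"q_G": np.nan, "q_T": 0.01, "q_GxT": 0.01}])
        assert pd.isna(assign_categories(df).iloc[0])


class TestGlmPairwise:
    def test_categories_partition_pairs(self, default_sim):
        _, cm, samples, truth = default_sim
        res = glm_pairwise(cm, samples, truth)
        assert res["category"].notna().all()
        assert res["category"].isin(list("i ii iii iv v vi vii viii".split())).all()
        assert len(res) == len(truth)

    def test_gxt_only_scenario_hits_interaction_not_gene(self):
        design = SimulationDesign(
            n_pairs=60, scenario_mix={"GxT": 1.0},
            interaction_log2fc=2.0, seed=15,
        )
        cm, samples, truth = simulate_counts(design)
        res = glm_pairwise(cm, samples, truth)
        assert (res["q_GxT"] <= 0.05).mean() >= 0.9
        assert (res["p_G"] > 0.05).mean() >= 0.9

    def test_relabeling_invariance(self):
        design = SimulationDesign(n_pairs=40, seed=16)
        cm, samples, truth = simulate_counts(design)
        res = glm_pairwise(cm, samples, truth)
        swapped = truth.rename(
            columns={"gene1_id": "gene2_id", "gene2_id": "gene1_id"}
        )
        res_sw = glm_pairwise(cm, samples, swapped)
        pd.testing.assert_series_equal(res["category"], res_sw["category"])
        for t in ("leaf", "petal", "seed"):
            np.testing.assert_allclose(
                res[f"prop_gene1_{t}"], 1.0 - res_sw[f"prop_gene1_{t}"], atol=1e-6
            )


class TestComplementary:
    def test_definition_on_constructed_results(self):
        base = {
            "q_GbyT_a": 0.01, "q_GbyT_b": 0.01,
            "prop_gene1_a": 0.6, "prop_gene1_b": 0.3,
        }
        df = pd.DataFrame(
            [
                {"pair_id": "p1", **base},  # reversed dominance -> call
                {"pair_id": "p2", **{**base, "prop_gene1_b": 0.7}},  # same side
                {"pair_id": "p3", **{**base, "q_GbyT_b": 0.5}},  # not DE in b
                {"pair_id": "p4", **{**base, "prop_gene1_a": 0.5}},  # no dominant
            ]
        )
        df.attrs["tissues"] = ["a", "b"]
        calls = detect_complementary(df)
        assert list(calls.pair_id) == ["p1"]
        assert calls.iloc[0].dominant_in_a == "gene1"
        assert calls.iloc[0].dominant_in_b == "gene2"

    def test_complementary_subset_of_double_significant(self, default_sim):
        _, cm, samples, truth = default_sim
        res = glm_pairwise(cm, samples, truth)
        calls = detect_complementary(res)
        qcols = {t: f"q_GbyT_{t}" for t in ("leaf", "petal", "seed")}
        res_i = res.set_index("pair_id")
        for rec in calls.itertuples():
            assert res_i.loc[rec.pair_id, qcols[rec.tissue_a]] <= 0.05
            assert res_i.loc[rec.pair_id, qcols[rec.tissue_b]] <= 0.05


class TestPooledAnova:
    def test_matches_statsmodels_on_tiny_layout(self):
        rng = np.random.default_rng(3)
        samples = pd.DataFrame(
            {
                "sample_id": ["A1", "A2", "B1", "B2"],
                "tissue": ["A", "A", "B", "B"],
                "replicate": [1, 2, 1, 2],
            }
        )
        pairs = pd.DataFrame(
            {"pair_id": ["p1", "p2"], "gene1_id": ["p1a", "p2a"],
             "gene2_id": ["p1b", "p2b"]}
        )
        genes = ["p1a", "p1b", "p2a", "p2b"]
        vals = pd.DataFrame(
            rng.normal(5, 1, size=(4, 4)), index=genes, columns=samples.sample_id
        )
        table = pooled_anova(vals, samples, pairs)

        long = vals.reset_index(names="gene").melt(
            id_vars="gene", var_name="sample_id", value_name="y"
        ).merge(samples)
        fit = smf.ols("y ~ C(gene) * C(tissue)", data=long).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        got = table.set_index("term")
        assert got.loc["Gene(G)", "sum_sq"] == pytest.approx(ref.loc["C(gene)", "sum_sq"])
        assert got.loc["Tissue(T)", "sum_sq"] == pytest.approx(
            ref.loc["C(tissue)", "sum_sq"]
        )
        assert got.loc["Gene:tissue(GxT)", "sum_sq"] == pytest.approx(
            ref.loc["C(gene):C(tissue)", "sum_sq"]
        )
        assert got.loc["Residuals", "sum_sq"] == pytest.approx(
            ref.loc["Residual", "sum_sq"]
        )
        assert got.loc["Gene(G)", "F"] == pytest.approx(ref.loc["C(gene)", "F"])

    def test_df_structure_at_paper_scale(self):
        """1,971 pairs x 3 tissues x 3 reps: gene df 3,941, interaction 7,882."""
        design = SimulationDesign(n_pairs=1971, seed=30)
        cm, samples, truth = simulate_counts(design)
        uq = upper_quartile(cm)
        vals = np.log2(uq.values + 0.5)
        table = pooled_anova(vals, samples, truth).set_index("term")
        assert table.loc["Gene(G)", "df"] == 3941
        assert table.loc["Tissue(T)", "df"] == 2
        assert table.loc["Gene:tissue(GxT)", "df"] == 7882
        n_obs = 1971 * 2 * 9
        assert table["df"].sum() == n_obs - 1

    def test_constant_values_flagged(self):
        samples = pd.DataFrame(
            {"sample_id": ["A1", "A2", "B1", "B2"],
             "tissue": ["A", "A", "B", "B"], "replicate": [1, 2, 1, 2]}
        )
        pairs = pd.DataFrame(
            {"pair_id": ["p1"], "gene1_id": ["p1a"], "gene2_id": ["p1b"]}
        )
        vals = pd.DataFrame(
            np.full((2, 4), 3.0), index=["p1a", "p1b"], columns=samples.sample_id
        )
        table = pooled_anova(vals, samples, pairs).set_index("term")
        assert table["sum_sq"].sum() == 0
        assert np.isnan(table.loc["Gene(G)", "F"])
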