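"""Normalization, log-ratio t-tests, BH, fold/overlap tables, silencing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from paleodup.expression import (
    CountsMatrix,
    bh_adjust,
    de_pairwise,
    detect_reciprocal_silencing,
    fold_change_table,
    overlap_summary,
    pair_log_ratios,
    pair_ttest,
    rpkm,
    upper_quartile,
)


def toy_counts():
    counts = pd.DataFrame(
        {"s1": [10, 20, 0, 30, 40], "s2": [20, 40, 0, 60, 80]},
        index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
    )
    lengths = pd.Series([1000] * 5, index=counts.index)
    return CountsMatrix(counts, lengths)


class TestRpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=pd.Index(["a", "b"]))
        cm = CountsMatrix(
            counts,
            pd.Series([1000, 500], index=counts.index),
            pd.Series([1e6], index=["s"]),
        )
        vals = rpkm(cm).values
        assert vals.loc["a", "s"] == pytest.approx(10.0)
        assert vals.loc["b", "s"] == 0.0

    def test_scale_invariance(self):
        cm = toy_counts()
        doubled = CountsMatrix(cm.counts * 2, cm.lengths, cm.totals * 2)
        pd.testing.assert_frame_equal(rpkm(cm).values, rpkm(doubled).values)

    def test_zero_total_errors(self):
        counts = pd.DataFrame({"s": [0]}, index=pd.Index(["a"]))
        cm = CountsMatrix(counts, pd.Series([100], index=["a"]))
        with pytest.raises(ValueError):
            rpkm(cm)


class TestUpperQuartile:
    def test_doubled_sample_normalizes_to_equal_columns(self):
        """Hand-checked 5-gene toy: factors 32.5 and 65, equal output."""
        nm = upper_quartile(toy_counts())
        assert nm.scale_factors["s1"] == pytest.approx(32.5)
        assert nm.scale_factors["s2"] == pytest.approx(65.0)
        np.testing.assert_allclose(nm.values["s1"], nm.values["s2"])

    def test_single_sample_identity(self):
        counts = pd.DataFrame({"s1": [10, 20, 30, 40]}, index=list("abcd"))
        nm = upper_quartile(CountsMatrix(counts, pd.Series([1000] * 4, index=counts.index)))
        np.testing.assert_allclose(nm.values["s1"], counts["s1"])

    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=list("ab"))
        with pytest.raises(ValueError):
            upper_quartile(CountsMatrix(counts, pd.Series([1000, 1000], index=list("ab"))))


class TestPairRatiosAndTtest:
    def test_identity_and_antisymmetry(self):
        cm = toy_counts()
        nm = rpkm(cm)
        r_fwd = pair_log_ratios(nm, "g0", "g1", ["s1", "s2"], pseudocount=0.0)
        r_rev = pair_log_ratios(nm, "g1", "g0", ["s1", "s2"], pseudocount=0.0)
        np.testing.assert_allclose(r_fwd, -r_rev)
        same = pair_log_ratios(nm, "g0", "g0", ["s1", "s2"], pseudocount=0.5)
        np.testing.assert_allclose(same, 0.0)

    def test_twofold_ratio(self):
        cm = toy_counts()
        nm = rpkm(cm)
        # g1 counts are exactly 2x g0 counts
        r = pair_log_ratios(nm, "g1", "g0", ["s1", "s2"], pseudocount=0.0)
        np.testing.assert_allclose(r, 1.0)

    def test_ttest_closed_form(self):
        t, df, p, degen = pair_ttest([0.5, 1.0, 1.5])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=1e-4)
        assert not degen
        # cross-check against the reference implementation
        ref = sps.ttest_1samp([0.5, 1.0, 1.5], 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_ttest_degenerate_cases(self):
        t, df, p, degen = pair_ttest([0.0, 0.0, 0.0])
        assert (t, p, degen) == (0.0, 1.0, True)
        t, df, p, degen = pair_ttest([1.0, 1.0, 1.0])
        assert p == 0.0 and degen

    def test_ttest_needs_two_ratios(self):
        with pytest.raises(ValueError):
            pair_ttest([0.5])


def bh_bruteforce(p, fdr):
    """Independent step-up oracle: largest k with p_(k) <= fdr*k/m."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= fdr * k / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    q = np.empty(m)
    prev = 1.0
    for k in range(m, 0, -1):
        prev = min(prev, p[order[k - 1]] * m / k)
        q[order[k - 1]] = prev
    return q, reject


class TestBH:
    def test_example_all_rejected(self):
        q, rej = bh_adjust([0.01, 0.02, 0.03, 0.04], fdr=0.05)
        assert rej.all()
        oq, orej = bh_bruteforce(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        np.testing.assert_allclose(q, oq)

    def test_all_ones_and_singleton(self):
        q, rej = bh_adjust([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not rej.any()
        q, rej = bh_adjust([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            if rng.random() < 0.3:
                p = np.round(p, 2)  # provoke ties
            q, rej = bh_adjust(p, fdr=0.05)
            oq, orej = bh_bruteforce(p, 0.05)
            np.testing.assert_allclose(q, oq, atol=1e-12)
            np.testing.assert_array_equal(rej, orej)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_q_values_bounded(self, p):
        q, _ = bh_adjust(p)
        assert ((q >= 0) & (q <= 1)).all()


class TestDePairwise:
    def test_de_direction_invariant_to_paralog_order(self, default_sim):
        _, cm, samples, truth = default_sim
        nm = rpkm(cm)
        de = de_pairwise(nm, truth, samples)
        swapped = truth.rename(
            columns={"gene1_id": "gene2_id", "gene2_id": "gene1_id"}
        )
        de_sw = de_pairwise(nm, swapped, samples)
        np.testing.assert_allclose(
            de["mean_log2_ratio"], -de_sw["mean_log2_ratio"], atol=1e-12
        )
        np.testing.assert_array_equal(de["reject"], de_sw["reject"])

    def test_low_expression_pairs_excluded(self, default_sim):
        _, cm, samples, truth = default_sim
        nm = rpkm(cm)
        de = de_pairwise(nm, truth, samples, min_expr=1e9)
        assert not de["tested"].any()
        assert de["q"].isna().all()

    def test_rpkm_and_uq_agree_under_strong_effects(self):
        from paleodup.synthetic import SimulationDesign, simulate_counts

        design = SimulationDesign(
            n_pairs=300, scenario_mix={"G_only": 0.5, "null": 0.5},
            effect_log2fc=3.0, seed=21,
        )
        cm, samples, truth = simulate_counts(design)
        de_r = de_pairwise(rpkm(cm), truth, samples)
        de_u = de_pairwise(upper_quartile(cm), truth, samples)
        a = set(de_r.loc[de_r.reject, ["pair_id", "tissue"]].itertuples(index=False))
        b = set(de_u.loc[de_u.reject, ["pair_id", "tissue"]].itertuples(index=False))
        overlap = len(a & b) / max(len(a | b), 1)
        assert overlap >= 0.9


class TestFoldChangeTable:
    def test_nesting_and_any_tissue(self, default_sim):
        _, cm, samples, truth = default_sim
        de = de_pairwise(rpkm(cm), truth, samples)
        tab = fold_change_table(de)
        for tissue in tab.index:
            row = tab.loc[tissue]
            assert row["fold_5"] <= row["fold_2"] <= row["fold_1.5"]
        for col in tab.columns:
            assert tab.loc["max_any_tissue", col] >= tab.drop("max_any_tissue")[col].max()

    def test_no_de_means_empty_table(self, null_sim):
        _, cm, samples, truth = null_sim
        de = de_pairwise(rpkm(cm), truth, samples)
        tab = fold_change_table(de)
        # under the complete null BH flags (almost) nothing
        assert tab.values.sum() <= 3

    def test_strong_g_only_fills_five_fold_cell(self):
        from paleodup.synthetic import SimulationDesign, simulate_counts

        design = SimulationDesign(
            n_pairs=300, scenario_mix={"G_only": 1.0}, effect_log2fc=3.0, seed=8
        )
        cm, samples, truth = simulate_counts(design)
        de = de_pairwise(rpkm(cm), truth, samples)
        tab = fold_change_table(de)
        for tissue in set(samples["tissue"]):
            assert tab.loc[tissue, "fold_5"] >= 0.95 * design.n_pairs


class TestOverlapSummary:
    def test_matches_bruteforce_sets(self, default_sim):
        _, cm, samples, truth = default_sim
        de = de_pairwise(rpkm(cm), truth, samples)
        summ = overlap_summary(de)
        sets = {
            t: set(sub.loc[sub.reject, "pair_id"]) for t, sub in de.groupby("tissue")
        }
        lookup = {(r.statistic, r.tissues): r.count for r in summ.itertuples()}
        for t, s in sets.items():
            assert lookup[("de_count", t)] == len(s)
        for a, b in itertools.combinations(sorted(sets), 2):
            assert lookup[("intersection", f"{a}&{b}")] == len(sets[a] & sets[b])
        allkey = "&".join(sorted(sets))
        assert lookup[("intersection", allkey)] == len(
            set.intersection(*sets.values())
        )

    def test_mismatched_universe_errors(self, default_sim):
        _, cm, samples, truth = default_sim
        de = de_pairwise(rpkm(cm), truth, samples)
        other = de[de["pair_id"] != truth["pair_id"].iloc[0]]
        with pytest.raises(ValueError):
            overlap_summary(de, other)


class TestSilencing:
    @staticmethod
    def _manual(norm_vals, de_flags, threshold=0.95):
        """Three-pair hand-constructed scenario."""
        genes = ["p1a", "p1b", "p2a", "p2b", "p3a", "p3b"]
        samples = pd.DataFrame(
            {
                "sample_id": ["A_r1", "A_r2", "B_r1", "B_r2"],
                "tissue": ["A", "A", "B", "B"],
                "replicate": [1, 2, 1, 2],
            }
        )
        pairs = pd.DataFrame(
            {
                "pair_id": ["p1", "p2", "p3"],
                "gene1_id": ["p1a", "p2a", "p3a"],
                "gene2_id": ["p1b", "p2b", "p3b"],
            }
        )
        from paleodup.expression import NormalizedMatrix

        nm = NormalizedMatrix(
            pd.DataFrame(norm_vals, index=genes, columns=samples.sample_id),
            "RPKM",
            pd.Series(1.0, index=samples.sample_id),
        )
        de = pd.DataFrame(
            [
                {"pair_id": p, "tissue": t, "reject": de_flags.get((p, t), True)}
                for p in pairs.pair_id
                for t in ["A", "B"]
            ]
        )
        return detect_reciprocal_silencing(nm, pairs, samples, de, threshold=threshold)

    def test_full_reversal_called_and_one_sided_not(self):
        vals = [
            [100, 100, 0, 0],    # p1a: all of pair in A, none in B
            [0, 0, 100, 100],    # p1b: reversed -> call
            [96, 96, 96, 96],    # p2a: dominant in both -> no call
            [4, 4, 4, 4],
            [100, 100, 100, 100],  # p3: equal split -> no call
            [100, 100, 100, 100],
        ]
        calls = self._manual(vals, {})
        assert list(calls.pair_id) == ["p1"]
        assert calls.iloc[0].dominant_gene_in_a != calls.iloc[0].dominant_gene_in_b

    def test_exact_boundary_inclusive(self):
        vals = [
            [95, 95, 5, 5],
            [5, 5, 95, 95],
            [50, 50, 50, 50], [50, 50, 50, 50],
            [50, 50, 50, 50], [50, 50, 50, 50],
        ]
        calls = self._manual(vals, {})
        assert list(calls.pair_id) == ["p1"]

    def test_requires_de_in_both_conditions(self):
        vals = [
            [100, 100, 0, 0],
            [0, 0, 100, 100],
            [50, 50, 50, 50], [50, 50, 50, 50],
            [50, 50, 50, 50], [50, 50, 50, 50],
        ]
        calls = self._manual(vals, {("p1", "B"): False})
        assert len(calls) == 0

    def test_zero_total_pair_excluded_with_warning(self):
        vals = [
            [0, 0, 0, 0],
            [0, 0, 0, 0],
            [50, 50, 50, 50], [50, 50, 50, 50],
            [50, 50, 50, 50], [50, 50, 50, 50],
        ]
        with pytest.warns(UserWarning, match="zero total"):
            calls = self._manual(vals, {})
        assert len(calls) == 0

    def test_monotone_in_threshold(self, default_sim):
        _, cm, samples, truth = default_sim
        nm = rpkm(cm)
        de = de_pairwise(nm, truth, samples)
        counts = [
            len(detect_reciprocal_silencing(nm, truth, samples, de, threshold=t))
            for t in (0.90, 0.95, 0.99)
        ]
        assert counts[0] >= counts[1] >= counts[2]
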