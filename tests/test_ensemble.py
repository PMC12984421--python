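import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uromethyl.ensemble import (
    FEATURE_NAMES,
    compare_with_mutation,
    decision_curve,
    ensemble_score,
    enumerate_subsets,
    net_benefit,
    roc_auc,
    select_best_subset,
    subset_search,
    threshold_at_specificity,
)


def auc_oracle(scores, labels):
    """Brute-force all-pairs concordance count, ties counted half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSubsets:
    def test_four_features_give_15(self):
        assert len(enumerate_subsets(FEATURE_NAMES)) == 15

    @pytest.mark.parametrize("n,count", [(1, 1), (2, 3), (3, 7)])
    def test_powerset_minus_empty(self, n, count):
        assert len(enumerate_subsets(FEATURE_NAMES[:n])) == count

    def test_deterministic_order(self):
        assert enumerate_subsets(("b", "a")) == [("a",), ("b",), ("a", "b")]


class TestEnsembleScore:
    def test_mean_of_two(self):
        s = {"methyl_score": 0.6, "cnv_score": 0.8, "gm_score": 0.1, "tumor_fraction": 0.0}
        assert ensemble_score(s, ("methyl_score", "cnv_score")) == pytest.approx(0.7)

    def test_singleton_identity(self):
        s = {"methyl_score": 0.37}
        assert ensemble_score(s, ("methyl_score",)) == pytest.approx(0.37)

    def test_constant_fixed_point(self):
        s = dict.fromkeys(FEATURE_NAMES, 0.42)
        for subset in enumerate_subsets(FEATURE_NAMES):
            assert ensemble_score(s, subset) == pytest.approx(0.42)

    def test_missing_feature_errors(self):
        with pytest.raises(ValueError):
            ensemble_score({"methyl_score": np.nan, "cnv_score": 0.5}, ("methyl_score", "cnv_score"))

    def test_dataframe_vectorized(self):
        df = pd.DataFrame({"methyl_score": [0.2, 0.6], "cnv_score": [0.4, 0.8]})
        np.testing.assert_allclose(
            ensemble_score(df, ("cnv_score", "methyl_score")), [0.3, 0.7]
        )

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_permutation_invariant(self, vals):
        s = dict(zip(FEATURE_NAMES, vals))
        for subset in enumerate_subsets(FEATURE_NAMES):
            v = ensemble_score(s, subset)
            sel = [s[f] for f in subset]
            assert min(sel) - 1e-12 <= v <= max(sel) + 1e-12
            assert v == pytest.approx(ensemble_score(s, tuple(reversed(subset))))


class TestBestSubset:
    def make_table(self, medians):
        rows = []
        for subset, med in medians.items():
            rows.append(
                {"subset": subset, "n_features": len(subset),
                 "repeat_aucs": [med], "median_auc": med}
            )
        return pd.DataFrame(rows)

    def test_argmax(self):
        tbl = self.make_table(
            {("methyl_score",): 0.8, ("cnv_score", "methyl_score"): 0.95, ("cnv_score",): 0.7}
        )
        assert select_best_subset(tbl) == ("cnv_score", "methyl_score")

    def test_tie_prefers_smaller_subset(self):
        tbl = self.make_table(
            {("cnv_score", "methyl_score"): 0.9, ("cnv_score", "gm_score", "methyl_score"): 0.9}
        )
        assert select_best_subset(tbl) == ("cnv_score", "methyl_score")

    def test_tie_same_size_lexicographic(self):
        tbl = self.make_table({("gm_score",): 0.9, ("cnv_score",): 0.9})
        assert select_best_subset(tbl) == ("cnv_score",)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_best_subset(pd.DataFrame())

    def test_complementary_signal_search(self):
        """Two informative out-of-fold scores with independent errors beat
        either alone; pure-noise features do not join the winner."""
        rng = np.random.default_rng(0)
        n = 60
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        folds = [[(np.array([]), np.arange(n))]]  # single pseudo-fold layout
        sig = y + rng.normal(0, 0.9, n)
        oof = {
            "methyl_score": (y + rng.normal(0, 0.8, n))[None, :],
            "cnv_score": (y + rng.normal(0, 0.8, n))[None, :],
            "gm_score": rng.normal(0, 1, n)[None, :],
            "tumor_fraction": rng.normal(0, 1, n)[None, :],
        }
        tbl = subset_search(oof, y, folds)
        assert len(tbl) == 15
        best = select_best_subset(tbl)
        assert "gm_score" not in best and "tumor_fraction" not in best


class TestROC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties(self):
        auc, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1])
        assert auc == 0.5

    def test_hand_enumerated_pairs(self):
        # concordant pairs: (0.5>0.3), (0.9>0.3), (0.9>0.6); discordant: (0.5<0.6)
        auc, _ = roc_auc([0.3, 0.6, 0.5, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            auc, _ = roc_auc(s, y)
            assert auc == pytest.approx(auc_oracle(s, y), abs=1e-12)


class TestThreshold:
    def test_80th_percentile_order_statistic(self):
        h = np.arange(20) / 20.0
        thr = threshold_at_specificity(h, 0.80)
        assert np.sum(h >= thr) == 4  # exactly 4 healthy called positive

    def test_target_one_no_false_positives(self):
        h = np.arange(10) / 10.0
        thr = threshold_at_specificity(h, 1.0)
        assert np.sum(h >= thr) == 0

    def test_ties_never_undershoot_specificity(self):
        h = np.array([0.2] * 10 + [0.4] * 10)
        thr = threshold_at_specificity(h, 0.80)
        spec = np.mean(h < thr)
        assert spec >= 0.80

    def test_bad_target_raises(self):
        with pytest.raises(ValueError):
            threshold_at_specificity(np.arange(10) / 10, 1.5)


class TestMutationComparison:
    def test_printed_counts_sensitivity(self):
        """30 mutation-positive of 37 cancers gives 81.1% sensitivity; with
        fully specific mutation calls, specificity is 100%."""
        labels = [1] * 37 + [0] * 20
        mutation = ["positive"] * 30 + ["negative"] * 7 + ["negative"] * 20
        calls = [False] * 57
        rep = compare_with_mutation(calls, mutation, labels)
        assert rep["mutation"]["sensitivity"] == pytest.approx(30 / 37)
        assert rep["mutation"]["specificity"] == 1.0

    def test_or_rule_rescues_mutation_negative(self):
        labels = [1, 1, 0]
        mutation = ["negative", "positive", "negative"]
        calls = [True, False, False]
        rep = compare_with_mutation(calls, mutation, labels)
        assert rep["combined_or"]["sensitivity"] == 1.0

    def test_both_negative_stays_negative(self):
        rep = compare_with_mutation([False], ["negative"], [1])
        assert rep["combined_or"]["tp"] == 0

    def test_or_combination_bounds(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = 40
            labels = rng.integers(0, 2, n)
            mutation = np.where(rng.random(n) < 0.5, "positive", "negative")
            calls = rng.random(n) < 0.4
            rep = compare_with_mutation(calls, mutation, labels)
            comb = rep["combined_or"]
            assert comb["sensitivity"] >= max(
                rep["mutation"]["sensitivity"], rep["ensemble"]["sensitivity"]
            ) - 1e-12
            assert comb["specificity"] <= min(
                rep["mutation"]["specificity"], rep["ensemble"]["specificity"]
            ) + 1e-12

    def test_unknown_status_excluded(self):
        with pytest.warns(UserWarning):
            rep = compare_with_mutation([True, False], ["positive", "unknown"], [1, 1])
        assert rep["n"] == 1


class TestDecisionCurve:
    def test_formula_arithmetic(self):
        assert net_benefit(30, 4, 57, 0.2) == pytest.approx(30 / 57 - (4 / 57) * 0.25)

    def test_low_pt_limit_approaches_tp_rate(self):
        scores = [0.9, 0.8, 0.1, 0.2]
        labels = [1, 1, 0, 0]
        curve = decision_curve(scores, labels, pt_grid=[0.001])
        assert curve["model"].iloc[0] == pytest.approx(2 / 4, abs=0.01)

    def test_treat_none_is_zero(self):
        curve = decision_curve([0.5, 0.6], [1, 0], pt_grid=[0.1, 0.5, 0.8])
        assert (curve["treat_none"] == 0).all()

    def test_pt_one_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], pt_grid=[1.0])

    def test_or_strategy_dominates_model_when_mutation_adds_tps(self):
        scores = [0.1, 0.9, 0.2, 0.15]
        labels = [1, 1, 0, 0]
        mut = np.array([True, False, False, False])
        curve = decision_curve(scores, labels, pt_grid=[0.3], or_calls=mut)
        assert curve["model_or_mutation"].iloc[0] >= curve["model"].iloc[0]
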