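"""Behavioral statistics: matrices, reliability, permutation null, tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facecontrast.analysis import (
    DegenerateTestError,
    UndefinedCorrelationError,
    compare_samples,
    condition_accuracy,
    learning_curves,
    matrix_correlation,
    pairwise_matrix,
    permutation_test,
    spearman_brown,
    split_half_reliability,
)
from facecontrast.behavior import DecisionModel, simulate_testing, simulate_training


def toy_trials(records):
    base = {
        "rat_id": "r1", "round": 1, "session_index": 0, "phase_or_protocol": "test1",
        "block_index": 1, "target_side": "left", "rewarded": True,
        "correction_trial": False, "pair_novelty": "new",
    }
    return pd.DataFrame([{**base, **r} for r in records])


class TestLearningCurves:
    def test_perfect_performer_stays_at_one(self, stimulus_set):
        trials = simulate_training(stimulus_set, DecisionModel(lapse=0.0, p_old=1.0), seed=0)
        curves = learning_curves(trials)
        assert (curves["accuracy"] == 1.0).all()

    def test_chance_performer_hovers_near_half(self, rng):
        rows = []
        for session in range(6):
            for _ in range(100):
                rows.append(
                    {
                        "rat_id": "r1", "round": 1, "session_index": session,
                        "phase_or_protocol": "phase1", "block_index": 0,
                        "target_id": "t", "distractor_id": "d", "target_side": "left",
                        "chose_target": bool(rng.random() < 0.5), "rewarded": True,
                        "correction_trial": False, "pair_novelty": "old",
                    }
                )
        curves = learning_curves(pd.DataFrame(rows))
        assert (abs(curves["accuracy"] - 0.5) < 4 * 0.05).all()

    def test_group_mean_equals_mean_of_per_rat_curves(self, stimulus_set):
        frames = []
        for rat in range(3):
            t = simulate_training(
                stimulus_set, DecisionModel(lapse=0.1, p_old=0.95), seed=rat, rat_id=f"rat{rat}"
            )
            frames.append(t)
        trials = pd.concat(frames, ignore_index=True)
        curves = learning_curves(trials)
        # recompute one point longhand
        row = curves.iloc[0]
        per_rat = []
        for rat in trials["rat_id"].unique():
            sub = trials[
                (trials["rat_id"] == rat)
                & (trials["phase_or_protocol"] == row["phase"])
                & (~trials["correction_trial"])
            ]
            first = sub["session_index"].min()
            per_rat.append(sub[sub["session_index"] == first]["chose_target"].mean())
        assert row["accuracy"] == pytest.approx(np.mean(per_rat))

    def test_no_training_trials_rejected(self, stimulus_set):
        trials = simulate_testing(stimulus_set, DecisionModel(), seed=0)
        with pytest.raises(ValueError):
            learning_curves(trials)


def exact_binom_two_sided(k, n):
    """Oracle: two-sided exact binomial p against 0.5 by direct pmf summation."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12))


class TestConditionAccuracy:
    @pytest.mark.parametrize("k,n", [(60, 100), (50, 100), (100, 100), (37, 80)])
    def test_exact_binomial_against_longhand_pmf_summation(self, k, n):
        cmap = {("t", "d"): "12 vs 1 CF"}
        trials = toy_trials(
            [{"target_id": "t", "distractor_id": "d", "chose_target": i < k} for i in range(n)]
        )
        out = condition_accuracy(trials, cmap)
        assert out.loc[0, "accuracy"] == pytest.approx(k / n)
        assert out.loc[0, "p_value"] == pytest.approx(exact_binom_two_sided(k, n), rel=1e-9)

    def test_degenerate_clopper_pearson_bound(self):
        cmap = {("t", "d"): "c"}
        trials = toy_trials(
            [{"target_id": "t", "distractor_id": "d", "chose_target": True}] * 100
        )
        out = condition_accuracy(trials, cmap)
        assert out.loc[0, "ci_low"] > 0.95
        assert out.loc[0, "ci_high"] == pytest.approx(1.0)

    def test_empty_condition_omitted_with_warning(self):
        cmap = {("t", "d"): "seen", ("t", "e"): "unseen"}
        trials = toy_trials([{"target_id": "t", "distractor_id": "d", "chose_target": True}] * 4)
        with pytest.warns(UserWarning, match="unseen"):
            out = condition_accuracy(trials, cmap)
        assert list(out["condition"]) == ["seen"]

    def test_consistent_with_pairwise_matrix_pooling(self, stimulus_set):
        """Condition accuracy equals the trial-weighted mean of its block's cells."""
        trials = simulate_testing(stimulus_set, DecisionModel(sensitivity=5, lapse=0.3), seed=8)
        cmap = stimulus_set.condition_map()
        mat = pairwise_matrix(
            trials,
            [im.id for im in stimulus_set.test_targets],
            [im.id for im in stimulus_set.test_distractors],
        )
        cond = condition_accuracy(trials, cmap).set_index("condition")
        for label in cond.index:
            cells = [
                (i, j)
                for i, t in enumerate(mat.row_labels)
                for j, d in enumerate(mat.col_labels)
                if cmap[(t, d)] == label
            ]
            w = np.array([mat.n_trials[c] for c in cells], dtype=float)
            v = np.array([mat.percent_correct[c] for c in cells])
            pooled = np.nansum(np.where(w > 0, v * w, 0)) / w.sum() / 100
            assert cond.loc[label, "accuracy"] == pytest.approx(pooled)


class TestPairwiseMatrix:
    def test_toy_log_three_of_four_correct(self):
        trials = toy_trials(
            [{"target_id": "t", "distractor_id": "d", "chose_target": c}
             for c in (True, True, True, False)]
        )
        m = pairwise_matrix(trials, ["t"], ["d"])
        assert m.percent_correct[0, 0] == pytest.approx(75.0)
        assert m.n_trials[0, 0] == 4

    def test_correction_trials_fully_excluded(self):
        recs = [{"target_id": "t", "distractor_id": "d", "chose_target": True}] * 2
        recs += [
            {"target_id": "t", "distractor_id": "d", "chose_target": False,
             "correction_trial": True}
        ] * 5
        m = pairwise_matrix(toy_trials(recs), ["t"], ["d"])
        assert m.percent_correct[0, 0] == pytest.approx(100.0)
        assert m.n_trials[0, 0] == 2

    def test_empty_cells_are_nan(self):
        trials = toy_trials([{"target_id": "t", "distractor_id": "d", "chose_target": True}])
        m = pairwise_matrix(trials, ["t"], ["d", "e"])
        assert np.isnan(m.percent_correct[0, 1])

    def test_pooled_equals_weighted_mean_of_rounds(self, stimulus_set):
        trials = simulate_testing(stimulus_set, DecisionModel(), seed=13)
        rows = [im.id for im in stimulus_set.test_targets]
        cols = [im.id for im in stimulus_set.test_distractors]
        pooled = pairwise_matrix(trials, rows, cols)
        r1 = pairwise_matrix(trials, rows, cols, rounds=[1])
        r2 = pairwise_matrix(trials, rows, cols, rounds=[2])
        n1, n2 = r1.n_trials, r2.n_trials
        expect = (np.nan_to_num(r1.percent_correct) * n1 + np.nan_to_num(r2.percent_correct) * n2)
        total = n1 + n2
        mask = total > 0
        np.testing.assert_allclose(
            pooled.percent_correct[mask], expect[mask] / total[mask], atol=1e-9
        )
        np.testing.assert_array_equal(pooled.n_trials, total)


class TestMatrixCorrelation:
    def test_affine_images_correlate_perfectly(self, rng):
        a = rng.normal(size=(10, 15))
        assert matrix_correlation(a, 2 * a + 3) == pytest.approx(1.0)
        assert matrix_correlation(a, -a) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(size=(10, 15))
        b = rng.normal(size=(10, 15))
        x, y = a.ravel(), b.ravel()
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert matrix_correlation(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            matrix_correlation(np.ones((3, 3)), np.arange(9.0).reshape(3, 3))

    def test_too_few_common_cells_rejected(self):
        a = np.full((2, 2), np.nan)
        a[0, 0] = a[0, 1] = 1.0
        with pytest.raises(UndefinedCorrelationError):
            matrix_correlation(a, a)


class TestReliability:
    def test_published_worked_example(self):
        assert round(spearman_brown(0.37), 2) == 0.54

    def test_fixed_points(self):
        assert spearman_brown(1.0) == pytest.approx(1.0)
        assert spearman_brown(0.0) == pytest.approx(0.0)

    def test_minus_one_rejected(self):
        with pytest.raises(ValueError):
            spearman_brown(-1.0)

    def test_split_half_is_plain_matrix_correlation(self, rng):
        a, b = rng.normal(size=(10, 15)), rng.normal(size=(10, 15))
        assert split_half_reliability(a, b) == matrix_correlation(a, b)


class TestPermutationTest:
    def test_identical_matrices_give_r_one_and_tiny_p(self, rng):
        a = rng.normal(size=(10, 15))
        res = permutation_test(a, a, n_perm=1000, seed=0)
        assert res.observed_r == pytest.approx(1.0)
        assert res.p_value <= 0.01

    def test_null_mean_near_zero_and_sd_near_one_over_sqrt_n_minus_one(self, rng):
        behavior = rng.uniform(0, 100, size=(10, 15))
        model = rng.normal(size=(10, 15))
        res = permutation_test(behavior, model, n_perm=1000, seed=1)
        se = res.null_sd / np.sqrt(res.n_perm)
        assert abs(res.null_mean) < 3 * se
        assert res.null_sd == pytest.approx(1 / np.sqrt(149), abs=0.01)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_null_variance_converges_to_one_over_n_minus_one(self, seed):
        rng = np.random.default_rng(seed)
        behavior = rng.normal(size=(6, 8))
        model = rng.normal(size=(6, 8))
        res = permutation_test(behavior, model, n_perm=3000, seed=seed)
        n = behavior.size
        sd_expected = 1 / np.sqrt(n - 1)
        # sd of a sample sd of ~normal null: sd/sqrt(2 n_perm)
        tol = 3 * sd_expected / np.sqrt(2 * res.n_perm) + 0.02
        assert abs(res.null_sd - sd_expected) < tol

    def test_p_counts_nulls_at_least_observed_without_smoothing(self, rng):
        a = rng.normal(size=(4, 4))
        b = rng.normal(size=(4, 4))
        res = permutation_test(a, b, n_perm=200, seed=3)
        assert res.p_value * res.n_perm == int(res.p_value * res.n_perm)

    def test_constant_behavior_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            permutation_test(np.ones((5, 5)), np.eye(5))


class TestCompareSamples:
    def test_identical_samples_give_t_zero_p_one(self):
        t, df, p = compare_samples([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_separated_samples_give_large_t(self):
        t, df, p = compare_samples([0.0, 0.001], [1.0, 0.999])
        assert abs(t) > 100
        assert p < 1e-4

    def test_matches_longhand_pooled_variance_formula(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(loc=0.4, size=5)
        t, df, p = compare_samples(x, y)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == len(x) + len(y) - 2

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(DegenerateTestError):
            compare_samples([1.0, 1.0], [2.0, 2.0])
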