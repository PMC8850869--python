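"""Evaluation harness: matching, prediction, GLS comparison, stability."""

import numpy as np
import pytest
from scipy import stats

import bigflica as bf
from bigflica.evaluate import greedy_match, nested_cv_predict, weighted_paired_ttest


class TestGreedyMatch:
    def test_permutation_and_sign_flip_gives_one(self):
        rng = np.random.default_rng(0)
        H = rng.standard_normal((100, 8))
        perm = rng.permutation(8)
        flip = np.where(rng.random(8) > 0.5, 1.0, -1.0)
        res = greedy_match(H[:, perm] * flip, H)
        assert res.mean_correlation == pytest.approx(1.0, abs=1e-12)
        # pairing undoes the permutation
        for e, t in res.pairing.items():
            assert perm[e] == t

    def test_independent_null_is_small(self):
        rng = np.random.default_rng(1)
        vals = [
            greedy_match(
                rng.standard_normal((500, 25)), rng.standard_normal((500, 25))
            ).mean_correlation
            for _ in range(5)
        ]
        assert np.mean(vals) < 0.1

    def test_tie_break_prefers_lower_estimated_index(self):
        h = np.array([1.0, 2.0, 3.0, 5.0])
        H_est = np.column_stack([h, h])  # identical columns -> tied |r|
        H_true = h[:, None]
        res = greedy_match(H_est, H_true)
        assert 0 in res.pairing and res.pairing[0] == 0

    def test_zero_variance_truth_errors(self):
        with pytest.raises(ValueError, match="truth"):
            greedy_match(np.random.default_rng(2).standard_normal((10, 2)), np.ones((10, 2)))

    def test_all_zero_estimated_components_excluded(self):
        rng = np.random.default_rng(3)
        H = rng.standard_normal((50, 3))
        est = np.column_stack([H[:, 0], np.zeros(50), H[:, 2]])
        res = greedy_match(est, H)
        assert 1 not in res.pairing
        assert len(res.pairing) == 2


class TestNestedCV:
    def test_planted_linear_signal_recovered(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((500, 30))
        beta = np.zeros(30)
        beta[[2, 11, 25]] = [1.0, -0.8, 0.6]
        y = X @ beta
        y = y + 0.01 * np.std(y) * rng.standard_normal(500)
        res = nested_cv_predict(X, y, seed=0)
        assert res.pearson_r > 0.9

    def test_null_phenotype_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((500, 30))
        rs = [
            nested_cv_predict(X, rng.standard_normal(500), seed=s).pearson_r
            for s in range(5)
        ]
        assert np.mean(np.abs(rs)) < 0.15

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((120, 10))
        y = X[:, 0] + 0.5 * rng.standard_normal(120)
        r1 = nested_cv_predict(X, y, seed=3)
        r2 = nested_cv_predict(X, y, seed=3)
        assert r1.pearson_r == r2.pearson_r
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_missing_phenotypes_dropped_not_imputed(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((200, 5))
        y = X[:, 0] + 0.1 * rng.standard_normal(200)
        y[::4] = np.nan
        res = nested_cv_predict(X, y, seed=0)
        assert res.subjects.size == 150
        assert np.all(np.isfinite(res.predictions))

    def test_screening_uses_training_folds_only(self):
        """Shuffling test-fold labels must not change the screened feature sets."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((150, 40))
        y = X[:, 5] + rng.standard_normal(150)
        base = nested_cv_predict(X, y, screen_k=10, seed=1)
        for f in np.unique(base.fold_assignments):
            y_shuf = y.copy()
            te = np.flatnonzero(base.fold_assignments == f)
            y_shuf[te] = y_shuf[rng.permutation(te)]
            pert = nested_cv_predict(X, y_shuf, screen_k=10, seed=1)
            np.testing.assert_array_equal(base.screened[f], pert.screened[f])

    def test_degenerate_phenotype_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            nested_cv_predict(np.random.default_rng(9).standard_normal((60, 4)), np.ones(60))


class TestWeightedPairedTTest:
    def test_equal_accuracies_give_t_zero_p_one(self):
        acc = np.linspace(0.2, 0.6, 20)
        res = weighted_paired_ttest(acc, acc.copy())
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_identity_V_reduces_to_paired_ttest(self):
        rng = np.random.default_rng(10)
        a = 0.3 + 0.1 * rng.standard_normal(40)
        b = 0.3 + 0.1 * rng.standard_normal(40)
        res = weighted_paired_ttest(a, b, r_threshold=-np.inf)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(t_ref, abs=1e-8)
        assert res.p_value == pytest.approx(p_ref, abs=1e-8)
        assert res.p1 == 40

    def test_exclusion_rule_drops_doubly_weak_phenotypes(self):
        a = np.array([0.05, 0.5, 0.02, 0.3])
        b = np.array([0.01, 0.4, 0.5, 0.2])
        res = weighted_paired_ttest(a, b)
        np.testing.assert_array_equal(res.retained, [1, 2, 3])
        assert res.p1 == 3

    def test_z_is_signed_inverse_normal_of_p(self):
        rng = np.random.default_rng(11)
        a = 0.3 + 0.05 * rng.standard_normal(30) + 0.03
        b = 0.3 + 0.05 * rng.standard_normal(30)
        res = weighted_paired_ttest(a, b, r_threshold=-np.inf)
        expect = np.sign(res.t) * stats.norm.isf(res.p_value / 2)
        assert res.z == pytest.approx(expect)

    def test_too_few_retained_errors(self):
        with pytest.raises(ValueError, match="retained"):
            weighted_paired_ttest([0.01, 0.02, 0.5], [0.02, 0.01, 0.4])


class TestPredictionStability:
    def test_deterministic_linear_phenotype_is_stable(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((300, 10))
        y = X @ np.array([1.0, -0.5, 0, 0, 0, 0, 0, 0, 0, 0.3])
        res = bf.prediction_stability(X, y, n_splits=3)
        assert np.all(np.abs(res["deviations"]) < 0.02)

    def test_deviations_center_on_zero_and_reproduce(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((200, 8))
        y = X[:, 0] + rng.standard_normal(200)
        res1 = bf.prediction_stability(X, y, n_splits=3, seeds=[1, 2, 3])
        res2 = bf.prediction_stability(X, y, n_splits=3, seeds=[1, 2, 3])
        np.testing.assert_allclose(res1["deviations"].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_array_equal(res1["accuracies"], res2["accuracies"])
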