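"""Metrics and statistical tests against independent counting oracles."""

import math

import numpy as np
import pytest

from pathocode.evaluation import (
    ConfusionMatrix,
    bootstrap_ci,
    cohen_kappa,
    compare_systems,
    error_rates,
    evaluate_predictions,
    f1_score,
    mcc,
    mcnemar_exact,
    one_sample_t,
    permutation_test,
    prf,
)


class TestPRF:
    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(["a", "b"], np.diag([5, 7]))
        r = prf(cm)
        assert r.macro_precision == r.macro_recall == r.macro_f1 == 1.0

    def test_f1_rounds_like_printed_pairs(self):
        # harmonic mean of a 0.97/0.90 precision-recall pair prints as 0.93
        assert round(f1_score(0.97, 0.90), 2) == 0.93
        assert round(f1_score(0.97, 0.98), 2) == 0.97
        assert round(f1_score(0.97, 0.99), 2) == 0.98

    def test_matches_counting_oracle_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            k = int(rng.integers(2, 8))
            m = rng.integers(0, 50, size=(k, k))
            m[rng.integers(k), rng.integers(k)] += 1  # non-empty
            cm = ConfusionMatrix([str(i) for i in range(k)], m)
            r = prf(cm)
            for i in range(k):
                tp = m[i, i]
                fp = m[:, i].sum() - tp
                fn = m[i, :].sum() - tp
                p = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / (tp + fn) if tp + fn else 0.0
                assert r.precision[str(i)] == pytest.approx(p)
                assert r.recall[str(i)] == pytest.approx(rec)
                assert r.f1[str(i)] == pytest.approx(f1_score(p, rec))


class TestErrorRates:
    def test_diagonal_matrix_all_zero(self):
        cm = ConfusionMatrix(["a", "b"], np.diag([3, 4]))
        assert all(v["absolute"] == 0 for v in error_rates(cm).values())

    def test_direct_count(self):
        m = np.array([[18, 2], [0, 0]])
        cm = ConfusionMatrix(["a", "b"], m)
        rates = error_rates(cm)
        assert rates["a"] == {"absolute": 2, "relative": 0.10, "support": 20}
        assert rates["b"]["relative"] is None

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 8))
            m = rng.integers(0, 30, size=(k, k))
            cm = ConfusionMatrix([str(i) for i in range(k)], m)
            rates = error_rates(cm)
            for i in range(k):
                absolute = int(sum(m[i, j] for j in range(k) if j != i))
                assert rates[str(i)]["absolute"] == absolute


class TestAgreement:
    def test_identical_vectors_kappa_one(self):
        assert cohen_kappa(["a", "b", "a"], ["a", "b", "a"]) == pytest.approx(1.0)

    def test_constant_prediction_on_balanced_gold_is_chance(self):
        assert cohen_kappa([0, 0, 1, 1], [1, 1, 1, 1]) == pytest.approx(0.0)

    def test_kappa_hand_example(self):
        # p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        assert cohen_kappa(list("AABB"), list("ABBB")) == pytest.approx(0.5)

    def test_mcc_perfect_and_inverse(self):
        assert mcc([0, 1, 0], [0, 1, 0]) == pytest.approx(1.0)
        assert mcc([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(-1.0)

    def test_mcc_binary_hand_value(self):
        # TP=1, FN=1, FP=0, TN=2 -> 2/sqrt(12)
        gold = [1, 1, 0, 0]
        pred = [1, 0, 0, 0]
        assert mcc(gold, pred) == pytest.approx(2 / math.sqrt(12))

    def test_degenerate_marginal_warns_zero(self):
        with pytest.warns(UserWarning):
            assert mcc([1, 1], [1, 0]) == 0.0

    def test_agree_with_sklearn_on_random_labelings(self):
        from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(2, 6))
            gold = rng.integers(0, k, size=n)
            pred = rng.integers(0, k, size=n)
            if len(set(gold)) < 2 or len(set(pred)) < 2:
                continue
            assert cohen_kappa(gold, pred) == pytest.approx(
                cohen_kappa_score(gold, pred), abs=1e-12)
            assert mcc(gold, pred) == pytest.approx(
                matthews_corrcoef(gold, pred), abs=1e-12)


class TestTTest:
    def test_symmetric_values_give_zero(self):
        t, p = one_sample_t([0.4, 0.6], mu0=0.5)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        t, p = one_sample_t([0.98, 0.99, 0.90], mu0=0.5)
        assert t == pytest.approx(16.0346, abs=1e-3)
        assert p < 0.01

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([0.7, 0.7, 0.7])


class TestMcNemar:
    def test_identical_vectors_p_one(self):
        with pytest.warns(UserWarning):
            b, c, p = mcnemar_exact([True, False], [True, False])
        assert (b, c, p) == (0, 0, 1.0)

    def test_two_discordant_one_direction(self):
        # b=0, c=2: two-sided p = 2 * P(X<=0 | n=2) = 0.5
        a = [True, True, False, False]
        b_vec = [True, True, True, True]
        b, c, p = mcnemar_exact(a, b_vec)
        assert (b, c) == (0, 2)
        assert p == pytest.approx(0.5)

    def test_balanced_discordance_p_one(self):
        a = [True, True, True, False, False, False]
        b_vec = [False, False, False, True, True, True]
        _, _, p = mcnemar_exact(a, b_vec)
        assert p == pytest.approx(1.0)

    def test_one_sided_tail(self):
        a = [False] * 11
        b_vec = [True] * 11
        _, _, p = mcnemar_exact(a, b_vec, alternative="one-sided")
        assert p == pytest.approx(0.5**11)


class TestPermutation:
    def test_equal_predictions_p_one(self):
        a = [True, False, True]
        assert permutation_test(a, a, n_perm=500, seed=0) == 1.0

    def test_symmetric_in_system_order(self):
        rng = np.random.default_rng(1)
        a = rng.random(40) < 0.8
        b = rng.random(40) < 0.5
        p1 = permutation_test(a, b, n_perm=2000, seed=7)
        p2 = permutation_test(b, a, n_perm=2000, seed=7)
        assert p1 == p2

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning):
            permutation_test([True], [False], n_perm=10, seed=0)


class TestBootstrap:
    def test_identical_units_degenerate_interval(self):
        lo, hi = bootstrap_ci([0.8] * 5, np.mean, n_boot=200, seed=0)
        assert lo == hi == pytest.approx(0.8)

    def test_interval_contains_point_estimate_for_mean(self):
        rng = np.random.default_rng(2)
        x = rng.random(30)
        lo, hi = bootstrap_ci(x, np.mean, n_boot=2000, seed=3)
        assert lo <= x.mean() <= hi


class TestCompareSystems:
    def test_identical_systems(self):
        gold = list("abcab")
        with pytest.warns(UserWarning):
            r = compare_systems(gold, gold, gold, n_perm=200, seed=0)
        assert r.accuracy_difference == 0.0
        assert r.mcnemar_p == 1.0
        assert r.permutation_p == 1.0

    def test_accuracy_difference_from_integer_counts(self):
        # 42 vs 31 correct of 53 -> printed difference 0.2075
        gold = ["g"] * 53
        preds_a = ["g"] * 42 + ["x"] * 11
        preds_b = ["g"] * 31 + ["x"] * 22
        r = compare_systems(gold, preds_a, preds_b, n_perm=500, seed=0)
        assert r.formatted()["accuracy_difference"] == 0.2075

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_systems(["a"], ["a"], ["a", "b"])

    def test_bit_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        gold = rng.integers(0, 3, 30).tolist()
        a = rng.integers(0, 3, 30).tolist()
        b = rng.integers(0, 3, 30).tolist()
        r1 = compare_systems(gold, a, b, n_perm=1000, seed=11)
        r2 = compare_systems(gold, a, b, n_perm=1000, seed=11)
        assert r1 == r2

    def test_accuracy_identity_with_confusion_total(self):
        rng = np.random.default_rng(6)
        gold = rng.integers(0, 4, 50).tolist()
        pred = rng.integers(0, 4, 50).tolist()
        report = evaluate_predictions(gold, pred)
        cm = ConfusionMatrix.from_pairs(gold, pred)
        assert report.accuracy == pytest.approx(np.trace(cm.matrix) / cm.matrix.sum())
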