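import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from seqentropy import (
    ClassifierSpec,
    ConfusionCounts,
    compare_classifiers,
    confusion,
    cross_validate,
    evaluate,
    fit_predict,
    pr_auc,
    roc_auc,
    scalar_metrics,
)
from seqentropy.classify import FAMILIES, default_roster
from seqentropy.exceptions import ConfigError, InputError, UndefinedMetricError
from seqentropy.synthetic import simulate_classification_set


class TestConfusion:
    def test_direct_count(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.FP == 0 and c.FN == 0

    def test_all_predicted_positive(self):
        c = confusion([1, 0, 0], [1, 1, 1])
        assert c.TN == 0 and c.FN == 0

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            confusion([1, 0], [1])


class TestScalarMetrics:
    def test_worked_example(self):
        m, flags = scalar_metrics(ConfusionCounts(TP=50, TN=40, FP=10, FN=0))
        assert m["ACC"] == pytest.approx(0.9)
        assert m["Sn"] == pytest.approx(1.0)
        assert m["Sp"] == pytest.approx(0.8)
        assert m["P"] == pytest.approx(0.833333, abs=1e-6)
        assert m["NPV"] == pytest.approx(1.0)
        assert m["MCC"] == pytest.approx(0.816497, abs=1e-6)
        assert not flags

    def test_perfect_prediction(self):
        m, _ = scalar_metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert m["ACC"] == 1.0 and m["MCC"] == 1.0

    def test_zero_denominator_flagged(self):
        m, flags = scalar_metrics(ConfusionCounts(TP=0, TN=3, FP=0, FN=2))
        assert m["P"] == 0.0 and "P" in flags and "MCC" in flags

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=60))
    def test_matches_brute_force_recount(self, pairs):
        y = [a for a, _ in pairs]
        p = [b for _, b in pairs]
        c = confusion(y, p)
        tp = sum(1 for a, b in pairs if a == 1 and b == 1)
        tn = sum(1 for a, b in pairs if a == 0 and b == 0)
        fp = sum(1 for a, b in pairs if a == 0 and b == 1)
        fn = sum(1 for a, b in pairs if a == 1 and b == 0)
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)
        m, _ = scalar_metrics(c)
        assert m["ACC"] == pytest.approx((tp + tn) / len(pairs))

    def test_mcc_invariant_under_class_and_prediction_swap(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        m1, _ = scalar_metrics(confusion(y, p))
        m2, _ = scalar_metrics(confusion(1 - y, 1 - p))
        assert m2["MCC"] == pytest.approx(m1["MCC"], abs=1e-12)
        assert m2["Sn"] == pytest.approx(m1["Sp"], abs=1e-12)
        assert m2["Sp"] == pytest.approx(m1["Sn"], abs=1e-12)


def _pairwise_auc(y, s):
    """Brute-force Mann–Whitney oracle over all pos-neg pairs."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRankingMetrics:
    def test_perfect_separation(self):
        assert roc_auc([1, 1, 0, 0], [4, 3, 2, 1]) == 1.0
        assert pr_auc([1, 1, 0, 0], [4, 3, 2, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 0], [0.5, 0.5]) == 0.5

    def test_worked_roc_example(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == pytest.approx(0.75)

    def test_worked_pr_example_average_precision_form(self):
        y, s = [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]
        assert pr_auc(y, s) == pytest.approx(5 / 6)
        assert pr_auc(y, s) == pytest.approx(average_precision_score(y, s))

    def test_all_positive_pr(self):
        assert pr_auc([1, 1, 1], [0.2, 0.9, 0.4]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1], [0.1, 0.2])
        with pytest.raises(UndefinedMetricError):
            pr_auc([0, 0], [0.1, 0.2])

    @settings(derandomize=True, max_examples=150)
    @given(st.integers(0, 10_000))
    def test_roc_matches_pairwise_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        # coarse scores force ties so the midrank path is exercised
        s = np.round(rng.random(n), 1)
        assert roc_auc(y, s) == pytest.approx(_pairwise_auc(y, s), abs=1e-12)
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_pr_matches_sklearn_average_precision(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 150))
        y = rng.integers(0, 2, n)
        if y.sum() == 0:
            y[0] = 1
        s = rng.random(n)
        assert pr_auc(y, s) == pytest.approx(average_precision_score(y, s), abs=1e-10)

    def test_random_scores_auprc_near_prevalence(self):
        rng = np.random.default_rng(0)
        n = 20_000
        y = (rng.random(n) < 0.3).astype(int)
        s = rng.random(n)
        assert pr_auc(y, s) == pytest.approx(y.mean(), abs=0.02)

    def test_gaussian_feature_auroc_matches_phi(self):
        from scipy.stats import norm

        # equal-variance 1-d Gaussians with mean gap delta = sigma
        rng = np.random.default_rng(1)
        n = 20_000
        y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
        s = np.r_[rng.standard_normal(n // 2) + 1.0, rng.standard_normal(n // 2)]
        assert roc_auc(y, s) == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.01)


class TestClassifiers:
    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierSpec(family="perceptron")

    def test_separable_margin_kernel_is_near_perfect(self):
        train = simulate_classification_set(4, 200, 200, mean_gap=6.0, seed=0)
        test = simulate_classification_set(4, 100, 100, mean_gap=6.0, seed=1)
        scores, pred = fit_predict(ClassifierSpec("margin-kernel"), train, test)
        rep = evaluate(test.labels, pred, scores)
        assert rep.ACC >= 0.99 and rep.auROC >= 0.99

    def test_single_class_train_rejected(self):
        train = simulate_classification_set(2, 4, 4, 1.0, seed=0)
        pos_only = train.subset(np.flatnonzero(train.labels == 1))
        with pytest.raises(InputError):
            fit_predict(ClassifierSpec("logistic"), pos_only, train)

    def test_dimension_mismatch_rejected(self):
        a = simulate_classification_set(2, 5, 5, 1.0, seed=0)
        b = simulate_classification_set(3, 5, 5, 1.0, seed=0)
        with pytest.raises(InputError):
            fit_predict(ClassifierSpec("logistic"), a, b)

    def test_same_seed_identical_scores(self):
        train = simulate_classification_set(3, 50, 50, 2.0, seed=0)
        test = simulate_classification_set(3, 30, 30, 2.0, seed=1)
        s1, p1 = fit_predict(ClassifierSpec("margin-kernel", seed=7), train, test)
        s2, p2 = fit_predict(ClassifierSpec("margin-kernel", seed=7), train, test)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_beats_chance_on_separable_data(self, family):
        train = simulate_classification_set(4, 120, 120, mean_gap=4.0, seed=2)
        test = simulate_classification_set(4, 60, 60, mean_gap=4.0, seed=3)
        scores, pred = fit_predict(ClassifierSpec(family), train, test)
        assert evaluate(test.labels, pred, scores).auROC > 0.95


class TestCrossValidation:
    def test_separable_cv_mean_acc(self):
        train = simulate_classification_set(4, 200, 200, mean_gap=6.0, seed=4)
        res = cross_validate(ClassifierSpec("margin-kernel"), train, seed=0)
        assert len(res.fold_metrics) == 5
        assert res.mean_metrics.ACC >= 0.99

    def test_mean_is_fieldwise_arithmetic_mean(self):
        train = simulate_classification_set(3, 60, 90, mean_gap=1.0, seed=5)
        res = cross_validate(ClassifierSpec("logistic"), train, seed=1)
        for name in ("ACC", "MCC", "auROC", "auPRC"):
            folds = [getattr(f, name) for f in res.fold_metrics]
            assert getattr(res.mean_metrics, name) == pytest.approx(
                np.mean(folds), abs=1e-12
            )

    def test_fold_determinism_and_class_too_small(self):
        train = simulate_classification_set(2, 40, 40, 2.0, seed=6)
        r1 = cross_validate(ClassifierSpec("logistic"), train, seed=3)
        r2 = cross_validate(ClassifierSpec("logistic"), train, seed=3)
        assert [f.as_dict() for f in r1.fold_metrics] == [
            f.as_dict() for f in r2.fold_metrics
        ]
        tiny = simulate_classification_set(2, 3, 40, 2.0, seed=6)
        with pytest.raises(InputError):
            cross_validate(ClassifierSpec("logistic"), tiny, folds=5)

    def test_independent_test_metrics_present(self):
        train = simulate_classification_set(3, 60, 60, 3.0, seed=7)
        test = simulate_classification_set(3, 40, 40, 3.0, seed=8)
        res = cross_validate(ClassifierSpec("logistic"), train, test=test, seed=0)
        assert res.test_metrics is not None
        assert res.test_metrics.ACC > 0.9


class TestCompare:
    def test_roster_rows_and_pairing(self):
        train = simulate_classification_set(3, 60, 60, 2.0, seed=9)
        results = compare_classifiers(default_roster(0), train, seed=0)
        assert [r.spec.family for r in results] == list(FAMILIES)
        # identical specs twice -> identical rows (shared folds)
        twice = compare_classifiers(
            [ClassifierSpec("logistic"), ClassifierSpec("logistic")], train, seed=0
        )
        assert twice[0].mean_metrics.as_dict() == twice[1].mean_metrics.as_dict()
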