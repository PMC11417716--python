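"""Metrics, threshold/weight optimization, splitting and pooled accuracy."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from sensorscreen.evaluate import (
    ConfusionCounts,
    SplitPlan,
    confusion,
    leave_one_third_out,
    mcc,
    optimize_sensor_weights,
    optimize_threshold,
    pooled_accuracy,
    roc_auc,
    sensitivity,
    specificity,
    split_train_test,
)


class TestConfusion:
    def test_separable_case_has_no_errors(self):
        c = confusion([2, 3, 0, -1], [True, True, False, False], 1.0)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_threshold_above_all_scores(self):
        c = confusion([0.1, 0.2], [True, False], 10.0)
        assert c.tp == 0 and c.fp == 0 and c.fn == 1 and c.tn == 1

    def test_boundary_score_counts_positive(self):
        c = confusion([1.0], [True], 1.0)
        assert c.tp == 1

    def test_matches_item_loop(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        t = 0.2
        tp = sum(s >= t and l for s, l in zip(scores, labels))
        fp = sum(s >= t and not l for s, l in zip(scores, labels))
        tn = sum(s < t and not l for s, l in zip(scores, labels))
        fn = sum(s < t and l for s, l in zip(scores, labels))
        c = confusion(scores, labels, t)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [], 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestMetrics:
    def test_perfect_classification(self):
        c = ConfusionCounts(tp=5, fp=0, tn=5, fn=0)
        assert sensitivity(c) == 1.0
        assert specificity(c) == 1.0
        assert mcc(c) == 1.0

    def test_label_independent_prediction_gives_mcc_zero(self):
        c = ConfusionCounts(tp=10, fp=10, tn=20, fn=20)
        assert mcc(c) == pytest.approx(0.0)

    def test_zero_denominator_factor_defined_as_zero(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=5, fn=5)) == 0.0

    def test_imbalanced_counts_match_arithmetic_oracle(self):
        # 89% sensitivity at 100 positives vs 1000 negatives, 10% FPR
        c = ConfusionCounts(tp=89, fn=11, fp=100, tn=900)
        expect = (89 * 900 - 100 * 11) / math.sqrt(
            (89 + 100) * (89 + 11) * (900 + 100) * (900 + 11)
        )
        assert mcc(c) == pytest.approx(expect)
        # and against scikit-learn on the reconstructed predictions
        y = [1] * 100 + [0] * 1000
        p = [1] * 89 + [0] * 11 + [1] * 100 + [0] * 900
        assert mcc(c) == pytest.approx(matthews_corrcoef(y, p))

    def test_mcc_in_range_and_one_iff_no_errors(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if (tp + fn) == 0 or (tn + fp) == 0:
                continue
            v = mcc(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert -1.0 <= v <= 1.0
            if fp == 0 and fn == 0:
                assert v == 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], [True, True, False, False]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 1, 1, 1], [True, False, True, False]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        for _ in range(100):
            scores = rng.normal(size=30)
            labels = rng.random(30) < 0.5
            if labels.all() or not labels.any():
                continue
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum(
                (1.0 if p > n else 0.5 if p == n else 0.0)
                for p, n in itertools.product(pos, neg)
            )
            oracle = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(oracle)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_negation_and_monotone_invariance(self, rng):
        scores = rng.normal(size=50)
        labels = np.concatenate([np.ones(20, bool), np.zeros(30, bool)])
        a = roc_auc(scores, labels)
        assert roc_auc(-scores, labels) == pytest.approx(1 - a)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(a)
        assert roc_auc(3 * scores + 7, labels) == pytest.approx(a)


def _exhaustive_best(scores, labels, objective="mcc"):
    """Independent oracle: scan every score value and +/- inf directly."""
    from sensorscreen.evaluate import confusion as conf

    candidates = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    best = -np.inf
    for t in candidates:
        c = conf(scores, labels, t)
        v = (
            mcc(c)
            if objective == "mcc"
            else sensitivity(c) + specificity(c) - 1
        )
        best = max(best, v)
    return best


class TestOptimizeThreshold:
    def test_separable_scores_reach_mcc_one(self):
        t, v = optimize_threshold([5, 6, 1, 2], [True, True, False, False])
        assert v == 1.0
        assert 2 < t <= 5

    def test_shuffled_labels_stay_near_zero(self, rng):
        scores = rng.normal(size=200)
        labels = rng.permutation([True] * 100 + [False] * 100)
        _, v = optimize_threshold(scores, labels)
        assert abs(v) < 0.3

    def test_objective_equals_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            _, v = optimize_threshold(scores, labels)
            assert v == pytest.approx(_exhaustive_best(scores, labels))

    def test_tie_breaks_to_lowest_threshold(self):
        t, v = optimize_threshold([1.0, 2.0], [False, True])
        assert t == pytest.approx(1.5)

    def test_youden_objective(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        if not (labels.any() and (~labels).any()):
            labels[0], labels[1] = True, False
        _, v = optimize_threshold(scores, labels, objective="youden")
        assert v == pytest.approx(_exhaustive_best(scores, labels, "youden"))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold([1, 2], [True, True])


class TestOptimizeSensorWeights:
    def test_single_sensor_weight_is_scale_invariant(self, rng):
        scores = rng.normal(size=50)[:, None]
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        w, _, v = optimize_sensor_weights(scores, labels)
        assert w[0] == 1.0  # no factor can beat the initial weight

    def test_informative_sensor_kept_noise_allowed_to_drop(self, rng):
        n = 120
        labels = np.arange(n) < 40
        informative = labels.astype(float) + rng.normal(0, 0.3, n)
        noise = rng.normal(size=n)
        matrix = np.column_stack([informative, noise])
        _, t_alone, v_alone = optimize_sensor_weights(
            matrix[:, :1], labels
        )
        w, _, v = optimize_sensor_weights(matrix, labels)
        assert w[0] > 0
        assert v >= v_alone

    def test_deterministic(self, rng):
        matrix = rng.normal(size=(60, 3))
        labels = rng.random(60) < 0.5
        labels[0], labels[1] = True, False
        a = optimize_sensor_weights(matrix, labels)
        b = optimize_sensor_weights(matrix, labels)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1] and a[2] == b[2]

    def test_objective_never_below_initial(self, rng):
        matrix = rng.normal(size=(80, 4))
        labels = rng.random(80) < 0.4
        labels[0], labels[1] = True, False
        _, _, v0 = optimize_sensor_weights(matrix, labels, grid=(1.0,))
        _, _, v = optimize_sensor_weights(matrix, labels)
        assert v >= v0

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            optimize_sensor_weights(
                np.ones((4, 1)), [True, False, True, False], grid=()
            )


class TestSplit:
    def test_nine_items_split_six_three(self):
        train, test = split_train_test(list("abcdefghi"), SplitPlan(seed=1))
        assert len(train) == 6 and len(test) == 3
        assert sorted(train + test) == sorted("abcdefghi")

    def test_seed_controls_split(self):
        ids = [f"i{k}" for k in range(30)]
        a = split_train_test(ids, SplitPlan(seed=5))
        b = split_train_test(ids, SplitPlan(seed=5))
        c = split_train_test(ids, SplitPlan(seed=6))
        assert a == b
        assert a != c

    def test_stratified_preserves_imbalance(self):
        ids = [f"p{k}" for k in range(20)] + [f"n{k}" for k in range(200)]
        labels = ["pos"] * 20 + ["neg"] * 200
        train, test = split_train_test(ids, SplitPlan(seed=2), labels)
        test_pos = sum(1 for i in test if i.startswith("p"))
        test_neg = len(test) - test_pos
        assert abs(test_pos - 20 / 3) <= 1
        assert abs(test_neg - 200 / 3) <= 1

    def test_tiny_class_stays_in_train(self):
        ids = ["a", "b", "c", "solo"]
        labels = ["x", "x", "x", "y"]
        train, test = split_train_test(ids, SplitPlan(seed=0), labels)
        assert "solo" in train

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(["a", "b"], SplitPlan())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(train_fraction=1.0)


def _mean_fit(X_train, y_train):
    centre = X_train[np.asarray(y_train)].mean(axis=0).to_numpy()
    return lambda X: -np.linalg.norm(X.to_numpy() - centre, axis=1)


class TestLeaveOneThirdOut:
    @pytest.fixture()
    def dataset(self, rng):
        pos = rng.normal(3, 1, size=(30, 2))
        neg = rng.normal(0, 1, size=(90, 2))
        X = pd.DataFrame(np.vstack([pos, neg]), columns=["a", "b"])
        y = np.arange(120) < 30
        return X, y

    def test_single_run_means_equal_that_run(self, dataset):
        X, y = dataset
        report, means = leave_one_third_out(X, y, _mean_fit, runs=1, seed=3)
        assert len(report) == 1
        for k in means:
            assert means[k] == pytest.approx(report[k].iloc[0])

    def test_fixed_seed_reproduces_all_runs(self, dataset):
        X, y = dataset
        a, _ = leave_one_third_out(X, y, _mean_fit, runs=3, seed=4)
        b, _ = leave_one_third_out(X, y, _mean_fit, runs=3, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_holdout_rejected(self, dataset):
        X, y = dataset
        with pytest.raises(ValueError, match="exceeds"):
            leave_one_third_out(X, y, _mean_fit, holdout_counts=(40, 10))

    def test_report_columns(self, dataset):
        X, y = dataset
        report, _ = leave_one_third_out(X, y, _mean_fit, runs=2, seed=1)
        assert list(report.columns) == [
            "run", "tp", "fp", "tn", "fn",
            "sensitivity", "specificity", "mcc", "auc",
        ]


class TestPooledAccuracy:
    def test_perfect_classes(self):
        assert pooled_accuracy([(10, 10), (5, 5)]) == 100.0

    def test_published_four_class_worked_example(self):
        # per-class TP counts reconstructed from rates on sizes 31/44/38/54
        assert pooled_accuracy([(21, 31), (39, 44), (31, 38), (48, 54)]) == 83.23

    def test_second_method_worked_example(self):
        value = pooled_accuracy([(29, 31), (44, 44), (35, 38), (53, 54)])
        assert value == 96.41
        assert round(value, 1) == 96.4

    def test_violated_precondition_rejected(self):
        with pytest.raises(ValueError):
            pooled_accuracy([(5, 4)])
        with pytest.raises(ValueError):
            pooled_accuracy([(0, 0)])
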