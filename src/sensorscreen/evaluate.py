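"""Model evaluation and optimization: MCC, ROC/AUC, thresholds, splits.

Binary decisions use the rule score >= threshold (items at the boundary
are called positive). The Matthews correlation coefficient with a zero
denominator factor is defined as 0, which keeps threshold optimization
total over degenerate thresholds. Sensor-battery weights are tuned by
coordinate ascent over a small multiplicative factor grid, re-optimizing
the decision threshold at every candidate — a discrete scheme that makes
the objective non-decreasing move by move and fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "SplitPlan",
    "confusion",
    "sensitivity",
    "specificity",
    "mcc",
    "roc_auc",
    "optimize_threshold",
    "optimize_sensor_weights",
    "split_train_test",
    "leave_one_third_out",
    "pooled_accuracy",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SplitPlan:
    """Train/test partition plan; default two-thirds train, stratified."""

    train_fraction: float = 2 / 3
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def _as_bool(labels) -> np.ndarray:
    return np.asarray(labels, dtype=bool)


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Count TP/FP/TN/FN at a threshold (positive iff score >= threshold)."""
    s = np.asarray(scores, dtype=float)
    y = _as_bool(labels)
    if s.shape != y.shape or s.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0.0 when there are no positives."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); 0.0 when there are no negatives."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 when any denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counted one half.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_bool(labels)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus below-min and
    above-max sentinels (all-positive / all-negative decisions)."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2 if distinct.size > 1 else np.array([])
    return np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))


def optimize_threshold(scores, labels, objective: str = "mcc") -> tuple[float, float]:
    """Exhaustively pick the decision threshold maximising MCC or Youden J.

    All midpoints between consecutive distinct scores are evaluated
    (plus sentinels below the minimum and above the maximum); ties go to
    the lowest threshold. Returns ``(threshold, objective_value)``.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_bool(labels)
    if not (y.any() and (~y).any()):
        raise ValueError("optimize_threshold needs both classes present")
    if objective not in ("mcc", "youden"):
        raise ValueError(f"unknown objective {objective!r}")

    best_t, best_v = None, -np.inf
    for t in _threshold_candidates(s):
        c = confusion(s, y, t)
        v = mcc(c) if objective == "mcc" else sensitivity(c) + specificity(c) - 1
        if v > best_v:
            best_t, best_v = float(t), float(v)
    return best_t, best_v


def optimize_sensor_weights(
    score_matrix,
    labels,
    grid=(0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    max_rounds: int = 10,
    objective: str = "mcc",
):
    """Coordinate-ascent tuning of per-sensor multiplicative weight factors.

    The combined score of an item is ``score_matrix @ weights``. Sensors
    are cycled in order; for each, every factor in ``grid`` is tried with
    the others held fixed, the decision threshold re-optimized at every
    trial, and the best factor kept. Stops after a full cycle with no
    improvement or ``max_rounds`` cycles. Deterministic given the input
    order; the objective never decreases on an accepted move.

    Returns ``(weights, threshold, objective_value)``.
    """
    m = np.asarray(score_matrix, dtype=float)
    y = _as_bool(labels)
    if m.ndim != 2 or m.shape[1] < 1:
        raise ValueError("score_matrix must be 2-D with >= 1 sensor column")
    if len(tuple(grid)) == 0:
        raise ValueError("weight grid must be non-empty")
    if not (y.any() and (~y).any()):
        raise ValueError("optimize_sensor_weights needs both classes present")

    n_sensors = m.shape[1]
    weights = np.ones(n_sensors)

    def evaluate(w):
        return optimize_threshold(m @ w, y, objective)

    best_t, best_v = evaluate(weights)
    for _ in range(max_rounds):
        improved = False
        for j in range(n_sensors):
            for g in grid:
                if g == weights[j]:
                    continue
                trial = weights.copy()
                trial[j] = g
                t, v = evaluate(trial)
                if v > best_v:
                    weights, best_t, best_v = trial, t, v
                    improved = True
        if not improved:
            break
    return weights, best_t, best_v


def split_train_test(ids, plan: SplitPlan, labels=None):
    """Seeded disjoint-exhaustive train/test split of item ids.

    With ``plan.stratified`` and labels given, each class is split
    separately so the test-set class ratio matches the full set within
    one item per class; a class with fewer than 2 members stays entirely
    in the training set (with a warning flag ignored here — it simply
    cannot be split).
    """
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 items to split")
    rng = np.random.default_rng(plan.seed)
    if plan.stratified and labels is not None:
        labels = np.asarray(labels)
        train, test = [], []
        for cls in pd.unique(labels):
            idx = [i for i, l in enumerate(labels) if l == cls]
            if len(idx) < 2:
                train.extend(idx)
                continue
            perm = rng.permutation(len(idx))
            n_train = int(round(plan.train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train.extend(idx[p] for p in perm[:n_train])
            test.extend(idx[p] for p in perm[n_train:])
        train.sort()
        test.sort()
        return [ids[i] for i in train], [ids[i] for i in test]
    perm = rng.permutation(len(ids))
    n_train = int(round(plan.train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = sorted(perm[:n_train])
    test = sorted(perm[n_train:])
    return [ids[i] for i in train], [ids[i] for i in test]


def leave_one_third_out(
    X: pd.DataFrame,
    labels,
    fit,
    runs: int = 3,
    holdout_counts: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Repeated random-holdout validation with per-class holdout sizes.

    For each run a holdout of ``holdout_counts = (n_positive,
    n_negative)`` items is drawn (default: one third of each class), the
    model is fitted on the remainder via ``fit(X_train, y_train) ->
    scorer`` where ``scorer(X) -> scores``, and sensitivity, specificity,
    MCC and AUC are measured on the holdout at the MCC-optimal training
    threshold. Returns a per-run DataFrame and a dict of means.
    """
    y = _as_bool(labels)
    idx_pos = np.flatnonzero(y)
    idx_neg = np.flatnonzero(~y)
    if holdout_counts is None:
        holdout_counts = (
            max(1, len(idx_pos) // 3),
            max(1, len(idx_neg) // 3),
        )
    n_hp, n_hn = holdout_counts
    if n_hp > len(idx_pos) or n_hn > len(idx_neg):
        raise ValueError(
            f"holdout ({n_hp} pos, {n_hn} neg) exceeds class sizes "
            f"({len(idx_pos)} pos, {len(idx_neg)} neg)"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(1, runs + 1):
        hold = np.concatenate(
            [
                rng.choice(idx_pos, size=n_hp, replace=False),
                rng.choice(idx_neg, size=n_hn, replace=False),
            ]
        )
        hold_mask = np.zeros(len(y), dtype=bool)
        hold_mask[hold] = True
        X_train, y_train = X[~hold_mask], y[~hold_mask]
        X_test, y_test = X[hold_mask], y[hold_mask]
        scorer = fit(X_train, y_train)
        train_scores = np.asarray(scorer(X_train), dtype=float)
        t, _ = optimize_threshold(train_scores, y_train)
        test_scores = np.asarray(scorer(X_test), dtype=float)
        c = confusion(test_scores, y_test, t)
        rows.append(
            {
                "run": run,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "sensitivity": sensitivity(c),
                "specificity": specificity(c),
                "mcc": mcc(c),
                "auc": roc_auc(test_scores, y_test),
            }
        )
    report = pd.DataFrame(rows)
    means = {
        k: float(report[k].mean())
        for k in ("sensitivity", "specificity", "mcc", "auc")
    }
    return report, means


def pooled_accuracy(per_class) -> float:
    """Overall accuracy (%) pooled over classes, to 2 decimals.

    ``per_class`` is a list of ``(true_positive_count, class_size)``
    pairs; the result is 100 * sum(tp) / sum(size).
    """
    total_tp = 0
    total = 0
    for tp_count, size in per_class:
        if size <= 0:
            raise ValueError("class_size must be positive")
        if not 0 <= tp_count <= size:
            raise ValueError("tp_count must be between 0 and class_size")
        total_tp += tp_count
        total += size
    return round(100.0 * total_tp / total, 2)
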