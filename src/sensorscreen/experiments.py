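"""Reference experiment protocols on the synthetic fixtures.

These functions wire the library end to end under the fixture study
conditions (four receptor-like classes of 20 sequences, length 300,
motif length 15, 2% substitution noise; 60:600 active/inactive
descriptor rows), so the same protocol backs the test suite, the
acceptance script and the worked examples in the README.
"""

from __future__ import annotations

import numpy as np

from .evaluate import SplitPlan, leave_one_third_out, roc_auc, split_train_test
from .models import classify_multiclass, raw_score, train_descriptor_model, train_sequence_models
from .simulate import gen_descriptor_dataset, gen_planted_motif_sequences

__all__ = [
    "multiclass_holdout_tp_rate",
    "descriptor_holdout_auc",
    "descriptor_validation_mcc",
]


def multiclass_holdout_tp_rate(
    seed: int = 17,
    n_classes: int = 4,
    n_per_class: int = 20,
    length: int = 300,
    motif_length: int = 15,
    mutation_rate: float = 0.02,
    max_iter: int = 8,
):
    """Holdout true-positive rate of the full multi-class pipeline.

    Generates the planted-motif fixture, splits it 2/3-1/3 stratified,
    nucleates one one-vs-rest sensor model per class (seed windows come
    from the generator's ground-truth placement of the first training
    sequence of each class — the expert-knowledge entry point), and
    classifies every holdout sequence by argmax raw score.

    Returns ``(percent_correct, n_holdout)``.
    """
    data = gen_planted_motif_sequences(
        n_classes=n_classes,
        n_per_class=n_per_class,
        length=length,
        motif_length=motif_length,
        mutation_rate=mutation_rate,
        seed=seed,
    )
    ids = [r.id for r in data.records]
    labels = [data.labels[i] for i in ids]
    train_ids, test_ids = split_train_test(
        ids, SplitPlan(train_fraction=2 / 3, seed=seed, stratified=True), labels
    )
    by_id = {r.id: r for r in data.records}
    train_seqs = [by_id[i] for i in train_ids]
    seeds = {}
    for cls in sorted(set(labels)):
        first = next(s for s in train_seqs if data.labels[s.id] == cls)
        seeds[cls] = [(first, data.placements[first.id])]
    models = train_sequence_models(
        train_seqs,
        {i: data.labels[i] for i in train_ids},
        seeds,
        window_length=motif_length,
        max_iter=max_iter,
        seed=seed,
    )
    correct = sum(
        classify_multiclass(models, by_id[i])[0] == data.labels[i] for i in test_ids
    )
    return 100.0 * correct / len(test_ids), len(test_ids)


def _fit_descriptor(X_train, y_train):
    model = train_descriptor_model(X_train, y_train)
    return lambda X: np.array([raw_score(model, row) for _, row in X.iterrows()])


def descriptor_holdout_auc(
    effect_size: float = 2.0,
    n_active: int = 60,
    n_inactive: int = 600,
    n_descriptors: int = 5,
    seed: int = 0,
) -> float:
    """Holdout ROC AUC of the descriptor activity model on one 2/3-1/3 split."""
    table, labels = gen_descriptor_dataset(
        n_active=n_active,
        n_inactive=n_inactive,
        n_descriptors=n_descriptors,
        effect_size=effect_size,
        seed=seed,
    )
    y = labels.to_numpy(dtype=bool)
    ids = list(table.index)
    train_ids, test_ids = split_train_test(
        ids, SplitPlan(train_fraction=2 / 3, seed=seed, stratified=True), y
    )
    scorer = _fit_descriptor(table.loc[train_ids], labels.loc[train_ids].to_numpy())
    scores = scorer(table.loc[test_ids])
    return roc_auc(scores, labels.loc[test_ids].to_numpy())


def descriptor_validation_mcc(
    effect_size: float = 2.0,
    n_active: int = 60,
    n_inactive: int = 600,
    n_descriptors: int = 5,
    runs: int = 3,
    holdout_counts: tuple[int, int] = (20, 200),
    seed: int = 0,
):
    """Leave-one-third-out validation of the descriptor activity model.

    The default 20/200 per-class holdout mirrors a 100/1000 holdout on
    a 300/3000 design, downscaled with the fixture. Returns the
    ``(per-run DataFrame, means dict)`` of
    :func:`sensorscreen.evaluate.leave_one_third_out`.
    """
    table, labels = gen_descriptor_dataset(
        n_active=n_active,
        n_inactive=n_inactive,
        n_descriptors=n_descriptors,
        effect_size=effect_size,
        seed=seed,
    )
    return leave_one_third_out(
        table,
        labels.to_numpy(dtype=bool),
        _fit_descriptor,
        runs=runs,
        holdout_counts=holdout_counts,
        seed=seed,
    )
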