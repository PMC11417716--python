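"""Trained sensor models: classification, activity indexing, ranking.

A :class:`SensorModel` bundles everything needed to score new items
reproducibly: the frozen encoding scheme, the sensors (or a seven-helix
battery), per-sensor weights, the decision threshold, and the training
score range used to map raw scores onto a 0-10 activity index.

The 0-10 index follows the hERG liability index (ELI) convention: raw
scores are min-max scaled over the training range and clipped, so 5.0 is
a natural screening threshold and ordering is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import (
    BLOCK,
    BinaryVector,
    EncodingScheme,
    SequenceRecord,
    build_descriptor_bins,
    encode_descriptors,
    encode_sequence,
)
from .evaluate import optimize_threshold
from .nucleation import (
    HelixBattery,
    combined_receptor_score,
    init_core,
    iterate_nucleation,
    sample_tn_windows,
)
from .sensors import VirtualSensor, sensor_score, train_sensor_weights

__all__ = [
    "SensorModel",
    "HierarchyNode",
    "raw_score",
    "classify_binary",
    "eli_index",
    "classify_hierarchical",
    "rank_candidates",
    "train_descriptor_model",
    "train_sequence_models",
    "classify_multiclass",
]


@dataclass
class SensorModel:
    """A trained classifier/indexer: scheme + sensors + weights + threshold.

    ``index_scale = (raw_min, raw_max)`` is the training-score range the
    0-10 activity index is anchored to; ``None`` disables indexing.
    ``battery`` replaces ``sensors`` for seven-helix receptor models.
    """

    scheme: EncodingScheme
    sensors: tuple = ()
    battery: HelixBattery | None = None
    sensor_weights: np.ndarray = field(default_factory=lambda: np.ones(1))
    threshold: float = 0.0
    index_scale: tuple[float, float] | None = None
    label_positive: str = "positive"

    def __post_init__(self) -> None:
        if self.battery is None and not self.sensors:
            raise ValueError("model needs sensors or a battery")
        if self.battery is None:
            self.sensors = tuple(self.sensors)
            self.sensor_weights = np.asarray(self.sensor_weights, dtype=float)
            if self.sensor_weights.shape != (len(self.sensors),):
                raise ValueError("one weight per sensor required")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.index_scale is not None:
            lo, hi = self.index_scale
            if not lo < hi:
                raise ValueError("index_scale requires raw_min < raw_max")


def _encode_item(model: SensorModel, item) -> BinaryVector:
    if isinstance(item, BinaryVector):
        return item
    if isinstance(item, SequenceRecord):
        return encode_sequence(item, model.scheme)
    if isinstance(item, (pd.Series, dict)):
        return encode_descriptors(item, model.scheme.bins)
    raise TypeError(f"cannot encode item of type {type(item).__name__}")


def raw_score(model: SensorModel, item) -> float:
    """Weighted sum of sensor scores for one item (battery: combined score)."""
    if model.battery is not None:
        if not isinstance(item, SequenceRecord):
            raise TypeError("battery models score SequenceRecord items")
        return combined_receptor_score(model.battery, item)
    vec = _encode_item(model, item)
    total = 0.0
    for w, sensor in zip(model.sensor_weights, model.sensors):
        total += w * sensor_score(sensor, vec).score
    return float(total)


def classify_binary(model: SensorModel, item) -> tuple[bool, float]:
    """Positive iff raw score >= threshold. Returns (is_positive, raw)."""
    raw = raw_score(model, item)
    return raw >= model.threshold, raw


def eli_index(model: SensorModel, item) -> float:
    """0-10 activity index: min-max over the training scores, clipped.

    Strictly increasing in the raw score inside the training range;
    scores at or beyond the range pin to 0 or 10.
    """
    if model.index_scale is None:
        raise ValueError("model has no index_scale; train with indexing enabled")
    lo, hi = model.index_scale
    raw = raw_score(model, item)
    return float(np.clip(10.0 * (raw - lo) / (hi - lo), 0.0, 10.0))


@dataclass
class HierarchyNode:
    """One level of a hierarchical classifier (family -> subfamily -> ...).

    ``models`` maps each child label to the SensorModel scoring it;
    ``children`` maps a label to the next-level node (leaves omitted).
    """

    level_name: str
    models: dict
    children: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.models) < 2:
            raise ValueError(
                f"hierarchy node {self.level_name!r} needs >= 2 child labels"
            )
        for label in self.children:
            if label not in self.models:
                raise ValueError(f"child {label!r} has no model at {self.level_name!r}")


def classify_hierarchical(
    root: HierarchyNode, item, abstain_margin: float = 0.0
) -> list[tuple[str, str, float]]:
    """Descend the hierarchy by per-node argmax of raw scores.

    At each node every child model scores the item; the best label wins
    with margin best minus second best (ties go to the lexicographically
    smallest label, margin 0). Descent stops early (abstains) when the
    margin falls below ``abstain_margin``. Returns
    ``[(level_name, label, margin), ...]`` along the path taken.
    """
    path = []
    node = root
    while node is not None:
        labels = sorted(node.models)
        scores = np.array([raw_score(node.models[l], item) for l in labels])
        order = np.argsort(-scores, kind="stable")  # stable: ties keep lex order
        best = int(order[0])
        margin = float(scores[best] - scores[int(order[1])])
        if margin < abstain_margin:
            break
        label = labels[best]
        path.append((node.level_name, label, margin))
        node = node.children.get(label)
    return path


def rank_candidates(model: SensorModel, items) -> list[tuple[str, float]]:
    """Rank items by descending raw score; ties keep input order.

    ``items`` is an iterable of ``(id, item)`` pairs or a DataFrame of
    descriptor rows (index = ids). Returns ``[(id, score), ...]``.
    """
    if isinstance(items, pd.DataFrame):
        pairs = [(str(i), row) for i, row in items.iterrows()]
    else:
        pairs = [(str(i), it) for i, it in items]
    scored = [(i, raw_score(model, it)) for i, it in pairs]
    scored.sort(key=lambda t: -t[1])  # sort is stable: ties keep input order
    return scored


def train_descriptor_model(
    table: pd.DataFrame,
    labels,
    n_bins: int = 5,
    pseudo: float = 0.5,
    label_positive: str = "active",
) -> SensorModel:
    """Train an activity model on a descriptor table (e.g. hERG liability).

    Bins are learned on this (training) table only, each row is one-hot
    encoded, and a single full-width fixed sensor is fitted with the
    positive rows as TP and the negative rows as TN segments. The
    decision threshold maximises training MCC and the training score
    range becomes the 0-10 index scale.
    """
    y = np.asarray(labels, dtype=bool)
    if len(table) != len(y):
        raise ValueError("table and labels must align")
    if not (y.any() and (~y).any()):
        raise ValueError("need both active and inactive rows")
    bins = tuple(build_descriptor_bins(table, n_bins=n_bins))
    scheme = EncodingScheme("descriptor", bins=bins)
    vecs = [encode_descriptors(row, bins) for _, row in table.iterrows()]
    tp = [v.bits for v, flag in zip(vecs, y) if flag]
    tn = [v.bits for v, flag in zip(vecs, y) if not flag]
    sensor = train_sensor_weights(
        tp, tn, pseudo=pseudo, sensor_id="activity", placement="fixed"
    )
    model = SensorModel(
        scheme=scheme,
        sensors=(sensor,),
        sensor_weights=np.ones(1),
        threshold=0.0,
        label_positive=label_positive,
    )
    scores = np.array([raw_score(model, v) for v in vecs])
    t, _ = optimize_threshold(scores, y)
    model.threshold = float(t)
    lo, hi = float(scores.min()), float(scores.max())
    if hi <= lo:
        hi = lo + 1.0
    model.index_scale = (lo, hi)
    return model


def train_sequence_models(
    sequences,
    labels: dict,
    seeds: dict,
    window_length: int,
    max_iter: int = 10,
    patience: int = 2,
    pseudo: float = 0.5,
    tn_factor: int = 10,
    seed: int = 0,
) -> dict:
    """One-vs-rest nucleation: one sliding-sensor model per class label.

    For each class, the class's training sequences are the nucleation
    training set, a seeded window pool from the other classes is the TN
    side, and the stopping rule validates class-vs-rest on the whole
    training set. ``seeds[label]`` supplies that class's initial core
    windows (the expert-knowledge entry point). Returns
    ``{label: SensorModel}``; classify with :func:`classify_multiclass`.
    """
    rng = np.random.default_rng(seed)
    class_labels = sorted(set(labels.values()))
    max_len = max(len(s) for s in sequences)
    scheme = EncodingScheme("sequence", max_length=max_len)
    models = {}
    for cls in class_labels:
        pos = [s for s in sequences if labels[s.id] == cls]
        neg = [s for s in sequences if labels[s.id] != cls]
        if not pos or not neg:
            raise ValueError(f"class {cls!r} needs positives and negatives")
        core0 = init_core(seeds[cls], window_length)
        pool = sample_tn_windows(
            neg,
            window_length,
            count=tn_factor * (len(core0) + max_iter),
            rng=rng,
            fallback_positives=pos,
        )
        val = (pos + neg, [True] * len(pos) + [False] * len(neg))
        result = iterate_nucleation(
            core0,
            pos,
            pool,
            val,
            max_iter=max_iter,
            patience=patience,
            pseudo=pseudo,
            sensor_id=f"{cls}",
            class_tag=str(cls),
        )
        models[cls] = SensorModel(
            scheme=scheme,
            sensors=(result.sensor,),
            sensor_weights=np.ones(1),
            threshold=result.threshold,
            label_positive=str(cls),
        )
    return models


def classify_multiclass(models: dict, item) -> tuple[str, dict]:
    """Assign the label whose one-vs-rest model scores highest.

    Ties go to the lexicographically smallest label. Returns
    ``(label, {label: raw_score})``.
    """
    scores = {cls: raw_score(m, item) for cls, m in sorted(models.items())}
    best = max(sorted(scores), key=lambda c: scores[c])
    return best, scores
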