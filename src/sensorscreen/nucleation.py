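"""Iterative sensor nucleation and the seven-helix receptor battery.

Nucleation grows a sensor from a small core of exemplar windows (chosen
from experimental knowledge or, in tests, from planted ground truth): a
sensor is trained on the current core against a negative window pool,
every training sequence is scanned with it, and the single
highest-scoring window not yet in the core is absorbed. The cycle
repeats until the validation MCC stops improving (patience), an
iteration cap is hit, or every window is already in the core.

For seven-transmembrane-helix receptors (GPCRs), one sensor is nucleated
per helix; a sequence's combined receptor score is the weighted sum of
the seven best helix matches, discounted when the matches do not appear
in the proper order along the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import BLOCK, EncodingScheme, SequenceRecord, encode_sequence
from .evaluate import optimize_threshold
from .sensors import VirtualSensor, _window_scores, train_sensor_weights

__all__ = [
    "Core",
    "HelixBattery",
    "NucleationExhausted",
    "NucleationResult",
    "init_core",
    "sequence_bits",
    "sample_tn_windows",
    "nucleation_step",
    "iterate_nucleation",
    "build_helix_battery",
    "check_helix_order",
    "battery_placements",
    "combined_receptor_score",
]


class NucleationExhausted(Exception):
    """Every candidate window of every training sequence is already in the core."""


def sequence_bits(seq: SequenceRecord) -> np.ndarray:
    """Full one-hot bit vector of a sequence (its own length as the scheme)."""
    scheme = EncodingScheme("sequence", max_length=len(seq))
    return encode_sequence(seq, scheme).bits


def _window_bits(seq: SequenceRecord, start: int, window_length: int) -> np.ndarray:
    if start < 0 or start + window_length > len(seq):
        raise ValueError(
            f"window [{start}, {start + window_length}) falls outside "
            f"sequence {seq.id!r} of length {len(seq)}"
        )
    sub = SequenceRecord(seq.id, seq.residues[start : start + window_length])
    return sequence_bits(sub)


@dataclass
class Core:
    """Exemplar window set a sensor is trained from.

    ``segments`` are the encoded windows (equal bit width, one 22-bit
    block per residue); ``provenance`` records where each came from as
    ``(sequence id, 0-based residue start)``; duplicates are stored once.
    """

    window_length: int
    segments: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.provenance):
            raise ValueError("segments and provenance must align")
        w = self.window_length * BLOCK
        for seg in self.segments:
            if np.asarray(seg).shape[0] != w:
                raise ValueError("all core segments must share the window length")

    def __len__(self) -> int:
        return len(self.segments)

    def add(self, segment: np.ndarray, origin: tuple[str, int]) -> bool:
        """Add a window unless its (id, start) is already present."""
        if origin in self.provenance:
            return False
        self.segments.append(np.asarray(segment, dtype=np.uint8))
        self.provenance.append(origin)
        return True

    def copy(self) -> "Core":
        return Core(
            self.window_length, list(self.segments), list(self.provenance)
        )


def init_core(seed_windows, window_length: int) -> Core:
    """Build a core from seed windows ``[(SequenceRecord, start), ...]``.

    Seeds are where domain knowledge enters: windows believed to contain
    the motif of interest. Duplicate (id, start) pairs are kept once.
    """
    if not seed_windows:
        raise ValueError("need at least one seed window")
    core = Core(window_length)
    for seq, start in seed_windows:
        core.add(_window_bits(seq, start, window_length), (seq.id, int(start)))
    return core


def sample_tn_windows(
    negatives,
    window_length: int,
    count: int,
    rng: np.random.Generator,
    fallback_positives=None,
):
    """Uniformly sample negative windows for sensor training.

    Draws ``count`` windows from random positions of random sequences in
    ``negatives``; when no negatives exist, windows are drawn from
    residue-shuffled copies of ``fallback_positives`` instead, which
    preserves composition while destroying motifs.
    """
    pool_seqs = list(negatives) if negatives else []
    if not pool_seqs:
        if not fallback_positives:
            raise ValueError("no negatives and no positives to shuffle")
        for seq in fallback_positives:
            letters = list(seq.residues)
            rng.shuffle(letters)
            pool_seqs.append(SequenceRecord(seq.id + "|shuffled", "".join(letters)))
    usable = [s for s in pool_seqs if len(s) >= window_length]
    if not usable:
        raise ValueError("no negative sequence is as long as the window")
    out = []
    for _ in range(count):
        seq = usable[int(rng.integers(len(usable)))]
        start = int(rng.integers(len(seq) - window_length + 1))
        out.append(_window_bits(seq, start, window_length))
    return out


def _scan_training(sensor, encoded, provenance_block):
    """Best not-yet-absorbed window over all training sequences.

    Ties resolve to the earliest sequence in list order, then the
    smallest start. Returns (seq_index, residue_start, score) or None.
    """
    best = None
    for i, (seq_id, bits, taken) in enumerate(encoded):
        scores = _window_scores(sensor, bits)
        if seq_id in provenance_block:
            blocked = provenance_block[seq_id]
            scores = scores.copy()
            for s in blocked:
                if 0 <= s < scores.shape[0]:
                    scores[s] = -np.inf
        j = int(np.argmax(scores))
        if not np.isfinite(scores[j]):
            continue
        if best is None or scores[j] > best[2]:
            best = (i, j, float(scores[j]))
    return best


def nucleation_step(core: Core, training, tn_pool, pseudo: float = 0.5):
    """One nucleation cycle: train a sensor on the core, absorb the best window.

    The sensor is trained with the core segments as positives and
    ``tn_pool`` as negatives, every training sequence is scanned, and
    the globally highest-scoring window whose (id, start) is not already
    in the core is added. Raises :class:`NucleationExhausted` when no
    window remains. Returns ``(core, sensor)`` with the core updated in
    place.
    """
    if not training:
        raise ValueError("training set must be non-empty")
    sensor = train_sensor_weights(
        core.segments, tn_pool, pseudo=pseudo, stride=BLOCK
    )
    encoded = [(seq.id, sequence_bits(seq), None) for seq in training]
    block: dict[str, set[int]] = {}
    for seq_id, start in core.provenance:
        block.setdefault(seq_id, set()).add(start)
    best = _scan_training(sensor, encoded, block)
    if best is None:
        raise NucleationExhausted("all training windows are already in the core")
    i, start, _score = best
    seq = training[i]
    core.add(_window_bits(seq, start, core.window_length), (seq.id, start))
    return core, sensor


@dataclass
class NucleationResult:
    """Outcome of :func:`iterate_nucleation`.

    ``sensor`` is the sensor with the best recorded validation MCC;
    ``threshold`` the MCC-optimal decision threshold found with it;
    ``history`` one dict per iteration (core size, validation MCC, best
    so far); ``stop_reason`` one of ``patience | max_iter | exhausted``.
    """

    sensor: VirtualSensor
    threshold: float
    mcc: float
    history: list
    stop_reason: str
    core: Core


def _max_window_score(sensor, bits) -> float:
    return float(_window_scores(sensor, bits).max())


def iterate_nucleation(
    core0: Core,
    training,
    tn_pool,
    validation,
    max_iter: int = 15,
    patience: int = 2,
    pseudo: float = 0.5,
    sensor_id: str = "sensor",
    class_tag: str = "",
) -> NucleationResult:
    """Run nucleation cycles until the validation MCC stops improving.

    ``validation`` is ``(sequences, boolean labels)`` with at least one
    item of each class; after every cycle the freshly trained sensor
    scores each validation sequence (best sliding-window SWS) and the
    MCC at the MCC-optimal threshold is recorded. The sensor with the
    best validation MCC is returned; patience counts consecutive cycles
    without improvement.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    val_seqs, val_labels = validation
    val_labels = np.asarray(val_labels, dtype=bool)
    if len(val_seqs) == 0:
        raise ValueError("validation set must be non-empty")
    if not (val_labels.any() and (~val_labels).any()):
        raise ValueError("validation needs both classes")
    val_bits = [sequence_bits(s) for s in val_seqs]

    core = core0.copy()
    best = None  # (mcc, sensor, threshold)
    history = []
    stale = 0
    stop_reason = "max_iter"
    for it in range(1, max_iter + 1):
        try:
            core, sensor = nucleation_step(core, training, tn_pool, pseudo=pseudo)
        except NucleationExhausted:
            stop_reason = "exhausted"
            break
        sensor = replace(sensor, id=f"{sensor_id}", class_tag=class_tag)
        scores = np.array([_max_window_score(sensor, b) for b in val_bits])
        t, v = optimize_threshold(scores, val_labels, "mcc")
        if best is None or v > best[0]:
            best = (v, sensor, t)
            stale = 0
        else:
            stale += 1
        history.append(
            {
                "iteration": it,
                "core_size": len(core),
                "validation_mcc": v,
                "best_mcc": best[0],
            }
        )
        if stale >= patience:
            stop_reason = "patience"
            break
    if best is None:
        raise NucleationExhausted(
            "nucleation exhausted before any sensor could be evaluated"
        )
    return NucleationResult(
        sensor=best[1],
        threshold=best[2],
        mcc=best[0],
        history=history,
        stop_reason=stop_reason,
        core=core,
    )


@dataclass
class HelixBattery:
    """Seven ordered helix sensors with per-sensor weights.

    ``min_gap`` is the minimum residue spacing between consecutive helix
    starts for a placement to count as properly ordered;
    ``order_penalty`` is the fraction of |score| subtracted when the
    order check fails (1.0 = hard rejection).
    """

    sensors: tuple
    sensor_weights: np.ndarray
    min_gap: int = 15
    order_penalty: float = 0.25
    converged: tuple = ()

    def __post_init__(self) -> None:
        self.sensors = tuple(self.sensors)
        if len(self.sensors) != 7:
            raise ValueError("a helix battery holds exactly 7 sensors (H1..H7)")
        self.sensor_weights = np.asarray(self.sensor_weights, dtype=float)
        if self.sensor_weights.shape != (7,):
            raise ValueError("need exactly 7 sensor weights")
        if not np.all(np.isfinite(self.sensor_weights)) or np.all(
            self.sensor_weights == 0
        ):
            raise ValueError("weights must be finite and not all zero")
        if np.any(self.sensor_weights < 0):
            raise ValueError("weights must be non-negative")


def check_helix_order(placements, min_gap: int) -> bool:
    """True iff the 7 starts are strictly increasing with gaps >= min_gap."""
    p = list(placements)
    if len(p) != 7:
        raise ValueError("expected 7 placements (H1..H7)")
    return all(b - a >= max(min_gap, 1) for a, b in zip(p, p[1:]))


def build_helix_battery(
    training,
    negatives,
    seeds,
    window_length: int,
    max_iter: int = 10,
    patience: int = 2,
    pseudo: float = 0.5,
    tn_factor: int = 10,
    seed: int = 0,
    min_gap: int = 15,
) -> HelixBattery:
    """Nucleate one sensor per transmembrane helix (7 seed-window sets).

    Each helix is nucleated independently with the positives as training
    set and a seeded uniform window pool from the negatives as the TN
    side; validation for the stopping rule is positives-vs-negatives.
    Battery weights start at 1 (tune with
    :func:`sensorscreen.evaluate.optimize_sensor_weights`). A helix that
    exhausts max_iter without a patience stop is still kept, flagged in
    ``converged``. Reusing one seed set for every helix yields seven
    identical sensors and a warning.
    """
    import warnings

    if len(seeds) != 7:
        raise ValueError("need exactly 7 seed-window sets")
    keyed = [tuple((s.id, int(st)) for s, st in sw) for sw in seeds]
    if len(set(keyed)) == 1 and len(seeds) > 1:
        warnings.warn(
            "identical seed windows supplied for all 7 helices; "
            "the battery will contain 7 identical sensors",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    val_seqs = list(training) + list(negatives)
    val_labels = [True] * len(training) + [False] * len(negatives)
    sensors = []
    converged = []
    for h, seed_windows in enumerate(seeds, start=1):
        core0 = init_core(seed_windows, window_length)
        pool = sample_tn_windows(
            negatives,
            window_length,
            count=tn_factor * (len(core0) + max_iter),
            rng=rng,
            fallback_positives=training,
        )
        result = iterate_nucleation(
            core0,
            training,
            pool,
            (val_seqs, val_labels),
            max_iter=max_iter,
            patience=patience,
            pseudo=pseudo,
            sensor_id=f"H{h}",
            class_tag=f"H{h}",
        )
        sensors.append(result.sensor)
        converged.append(result.stop_reason != "max_iter")
    return HelixBattery(
        sensors=tuple(sensors),
        sensor_weights=np.ones(7),
        min_gap=min_gap,
        converged=tuple(converged),
    )


def battery_placements(battery: HelixBattery, seq: SequenceRecord):
    """Best (residue start, score) of each helix sensor along a sequence."""
    bits = sequence_bits(seq)
    placements = []
    for sensor in battery.sensors:
        if bits.shape[0] < sensor.window_length:
            raise ValueError(
                f"sequence {seq.id!r} is shorter than the sensor window"
            )
        scores = _window_scores(sensor, bits)
        j = int(np.argmax(scores))
        placements.append((j, float(scores[j])))
    return placements


def combined_receptor_score(battery: HelixBattery, seq: SequenceRecord) -> float:
    """Weighted sum of the 7 best helix matches, order-penalised.

    When the seven best starts are not strictly increasing with at least
    ``min_gap`` residues between them, ``order_penalty`` times the
    absolute sum is subtracted (order_penalty 1.0 zeroes/negates any
    positive score — hard rejection).
    """
    placements = battery_placements(battery, seq)
    starts = [p[0] for p in placements]
    scores = np.array([p[1] for p in placements])
    total = float(np.dot(battery.sensor_weights, scores))
    if not check_helix_order(starts, battery.min_gap):
        total -= battery.order_penalty * abs(total)
    return total
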