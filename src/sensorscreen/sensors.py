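"""Virtual sensors: windowed bit patterns scored by weighted XNOR/XOR.

A virtual sensor is a reference bit pattern of window length W plus W
per-bit weights (the sensor weight score, SWS, components). Against a
candidate segment it computes, in positive (TP) mode, the weight-summed
XNOR — rewarding bits that agree with the pattern — and in negative (TN)
mode the weight-summed XOR. Because XNOR and XOR partition the window,
the two modes always sum to the total weight.

Weights are trained as per-bit log-odds (base 2, pseudo-count smoothed)
of pattern agreement in positive versus negative example segments, so a
high sliding-window score marks a segment that looks like the positives
and unlike the negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encoding import BinaryVector

__all__ = [
    "VirtualSensor",
    "SegmentMatch",
    "xnor_bits",
    "xor_bits",
    "segment_sws",
    "sensor_score",
    "train_sensor_weights",
]


@dataclass(frozen=True)
class VirtualSensor:
    """A scoring unit: bit pattern + per-bit SWS weights + placement rule.

    ``placement`` is ``"sliding"`` (best window anywhere, scanned every
    ``stride`` bits) or ``"fixed"`` (scored at ``start`` only). Sequence
    sensors use ``stride`` equal to the per-position block width so that
    windows never straddle residue-block boundaries; descriptor sensors
    are fixed at 0 and span the whole vector.
    """

    id: str
    pattern: np.ndarray
    weights: np.ndarray
    placement: str = "sliding"
    start: int = 0
    stride: int = 1
    class_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pattern", np.ascontiguousarray(self.pattern, dtype=np.uint8)
        )
        object.__setattr__(
            self, "weights", np.ascontiguousarray(self.weights, dtype=np.float64)
        )
        if self.pattern.ndim != 1 or self.pattern.shape != self.weights.shape:
            raise ValueError("pattern and weights must be 1-D and equal length")
        if self.pattern.shape[0] < 1:
            raise ValueError("window length must be positive")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.placement not in ("sliding", "fixed"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.stride < 1:
            raise ValueError("stride must be positive")

    @property
    def window_length(self) -> int:
        return int(self.pattern.shape[0])


@dataclass(frozen=True)
class SegmentMatch:
    """Where a sensor matched (0-based bit offset) and how strongly."""

    start: int
    score: float


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    aa = np.asarray(a, dtype=np.uint8)
    bb = np.asarray(b, dtype=np.uint8)
    if aa.shape != bb.shape:
        raise ValueError(f"length mismatch: {aa.shape[0]} vs {bb.shape[0]}")
    return aa, bb


def xnor_bits(a, b) -> np.ndarray:
    """Bitwise XNOR: 1 where the inputs agree."""
    aa, bb = _check_pair(a, b)
    return np.where(aa == bb, 1, 0).astype(np.uint8)


def xor_bits(a, b) -> np.ndarray:
    """Bitwise XOR: 1 where the inputs differ."""
    aa, bb = _check_pair(a, b)
    return np.where(aa != bb, 1, 0).astype(np.uint8)


def segment_sws(sensor: VirtualSensor, segment, mode: str = "TP") -> float:
    """Sensor weight score of one window-length segment.

    TP mode sums weights over agreeing bits (XNOR); TN mode over
    disagreeing bits (XOR). The two always add up to ``weights.sum()``.
    """
    seg = np.asarray(
        segment.bits if isinstance(segment, BinaryVector) else segment,
        dtype=np.uint8,
    )
    if seg.shape[0] != sensor.window_length:
        raise ValueError(
            f"segment length {seg.shape[0]} != window length {sensor.window_length}"
        )
    if mode == "TP":
        agree = xnor_bits(sensor.pattern, seg)
    elif mode == "TN":
        agree = xor_bits(sensor.pattern, seg)
    else:
        raise ValueError(f"mode must be 'TP' or 'TN', got {mode!r}")
    return float(np.dot(sensor.weights, agree))


def _window_scores(sensor: VirtualSensor, bits: np.ndarray) -> np.ndarray:
    """TP-mode SWS of every stride-aligned window, vectorised.

    XNOR against the pattern is affine in the segment:
    sum_p w_p * xnor(pat, seg)_p = sum_p w_p (1 - pat_p)
                                 + sum_p w_p (2 pat_p - 1) seg_p,
    so all window scores reduce to one matrix-vector product.
    """
    w = sensor.window_length
    const = float(np.dot(sensor.weights, 1 - sensor.pattern.astype(np.float64)))
    coef = sensor.weights * (2.0 * sensor.pattern - 1.0)
    windows = sliding_window_view(bits, w)[:: sensor.stride]
    return windows.astype(np.float64) @ coef + const


def sensor_score(sensor: VirtualSensor, item) -> SegmentMatch:
    """Best TP-mode match of the sensor against a full binary vector.

    Sliding placement returns the maximum windowed SWS and its 0-based
    bit start (earliest start on ties); fixed placement scores the
    declared start only.
    """
    bits = np.asarray(
        item.bits if isinstance(item, BinaryVector) else item, dtype=np.uint8
    )
    w = sensor.window_length
    if bits.shape[0] < w:
        raise ValueError(
            f"item width {bits.shape[0]} is shorter than sensor window {w}"
        )
    if sensor.placement == "fixed":
        seg = bits[sensor.start : sensor.start + w]
        return SegmentMatch(sensor.start, segment_sws(sensor, seg, "TP"))
    scores = _window_scores(sensor, bits)
    best = int(np.argmax(scores))  # argmax returns the first (smallest) start
    return SegmentMatch(best * sensor.stride, float(scores[best]))


def train_sensor_weights(
    tp_segments,
    tn_segments,
    pseudo: float = 0.5,
    sensor_id: str = "sensor",
    placement: str = "sliding",
    stride: int = 1,
    class_tag: str = "",
) -> VirtualSensor:
    """Fit a sensor from positive and negative example segments.

    The pattern is the per-bit majority among the positives (ties set
    the bit). Each weight is the base-2 log-odds of agreeing with the
    pattern in positives versus negatives,

        w_p = log2((f_TP,p + pseudo) / (f_TN,p + pseudo)),

    where f is the fraction of segments whose bit p equals the pattern
    bit. Any ``pseudo > 0`` keeps weights finite.
    """
    tp = np.asarray(
        [s.bits if isinstance(s, BinaryVector) else s for s in tp_segments],
        dtype=np.uint8,
    )
    tn = np.asarray(
        [s.bits if isinstance(s, BinaryVector) else s for s in tn_segments],
        dtype=np.uint8,
    )
    if tp.ndim != 2 or tp.shape[0] == 0:
        raise ValueError("tp_segments must be a non-empty list of equal-length segments")
    if tn.ndim != 2 or tn.shape[0] == 0:
        raise ValueError("tn_segments must be a non-empty list of equal-length segments")
    if tp.shape[1] != tn.shape[1]:
        raise ValueError(
            f"window mismatch: TP width {tp.shape[1]} vs TN width {tn.shape[1]}"
        )
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0 to keep weights finite")
    pattern = (tp.mean(axis=0) >= 0.5).astype(np.uint8)  # tie -> 1
    f_tp = (tp == pattern).mean(axis=0)
    f_tn = (tn == pattern).mean(axis=0)
    weights = np.log2((f_tp + pseudo) / (f_tn + pseudo))
    return VirtualSensor(
        id=sensor_id,
        pattern=pattern,
        weights=weights,
        placement=placement,
        stride=stride,
        class_tag=class_tag,
    )
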