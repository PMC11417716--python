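"""Binary encoding of protein sequences and molecular descriptor tables.

Every item handled by the toolkit — an amino-acid sequence or a row of
numeric molecular descriptors (molecular weight, logP, H-bond counts, ...)
— is mapped to a fixed-width binary vector. A sequence scheme allots one
block of 22 bits (20 amino acids + gap + unknown) per aligned position; a
descriptor scheme allots one block per descriptor, one bit per value bin,
so each block is one-hot. Downstream, virtual sensors score windows of
these vectors, so the block layout is frozen into the scheme and travels
with any trained model.

Also provides Tanimoto fingerprint similarity and the nearest-neighbour
diversity fraction used to characterise screening libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "GAP",
    "UNKNOWN",
    "BLOCK",
    "SequenceRecord",
    "DescriptorBinSpec",
    "EncodingScheme",
    "BinaryVector",
    "build_descriptor_bins",
    "encode_sequence",
    "decode_sequence",
    "encode_descriptors",
    "extract_frames",
    "tanimoto",
    "diversity_fraction",
]

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
#: Fixed residue alphabet: 20 amino acids, then gap, then unknown.
ALPHABET = AMINO_ACIDS + GAP + UNKNOWN
#: Bits per sequence position (one per alphabet symbol).
BLOCK = len(ALPHABET)

_SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence over the residue alphabet.

    Gaps are legal only in aligned contexts; plain FASTA readers reject
    them so that frame extraction never silently shifts.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues):
            if ch not in _SYMBOL_INDEX:
                raise ValueError(
                    f"sequence {self.id!r}: character {ch!r} at position {pos} "
                    f"is not in the residue alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DescriptorBinSpec:
    """Cut points turning one numeric descriptor into a one-hot block.

    ``edges`` are strictly increasing values in the descriptor's own units
    (e.g. daltons for molecular weight). ``len(edges) - 1`` interior bins
    are bounded on both sides; the outermost two bins are open-ended, so
    any real value — including test-set values outside the training range
    — lands in exactly one bin. A constant training column yields a
    flagged single-bin degenerate spec instead.
    """

    descriptor_name: str
    edges: tuple[float, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.degenerate:
            return
        if len(self.edges) < 2:
            raise ValueError(
                f"descriptor {self.descriptor_name!r}: need >= 2 bin edges, "
                f"got {len(self.edges)}"
            )
        arr = np.asarray(self.edges, dtype=float)
        if not np.all(np.diff(arr) > 0):
            raise ValueError(
                f"descriptor {self.descriptor_name!r}: edges must be strictly increasing"
            )

    @property
    def n_bins(self) -> int:
        if self.degenerate:
            return 1
        return len(self.edges) + 1

    def bin_index(self, value: float) -> int:
        """0-based bin for ``value``; bin 0 is the open low end."""
        if self.degenerate:
            return 0
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(
                f"descriptor {self.descriptor_name!r}: cannot bin NaN"
            )
        return int(np.searchsorted(self.edges, value, side="right"))


@dataclass(frozen=True)
class EncodingScheme:
    """Frozen block layout mapping items to fixed-width binary vectors.

    ``mode`` is ``"sequence"`` (one 22-bit block per position, up to
    ``max_length``) or ``"descriptor"`` (one block per
    :class:`DescriptorBinSpec`). The layout is serialized with any trained
    model so that scoring is reproducible bit for bit.
    """

    mode: str
    max_length: int | None = None
    bins: tuple[DescriptorBinSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode == "sequence":
            if not self.max_length or self.max_length < 1:
                raise ValueError("sequence scheme needs max_length >= 1")
        elif self.mode == "descriptor":
            if not self.bins:
                raise ValueError("descriptor scheme needs at least one bin spec")
        else:
            raise ValueError(f"unknown scheme mode {self.mode!r}")

    @property
    def block_sizes(self) -> tuple[int, ...]:
        if self.mode == "sequence":
            return (BLOCK,) * self.max_length
        return tuple(b.n_bins for b in self.bins)

    @property
    def width(self) -> int:
        return sum(self.block_sizes)

    @property
    def scheme_id(self) -> str:
        if self.mode == "sequence":
            return f"seq:{self.max_length}x{BLOCK}"
        names = ",".join(f"{b.descriptor_name}:{b.n_bins}" for b in self.bins)
        return f"desc:{names}"


@dataclass(frozen=True)
class BinaryVector:
    """A fixed-width 0/1 vector tied to the scheme that produced it."""

    bits: np.ndarray
    scheme_id: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bits", np.ascontiguousarray(np.asarray(self.bits, dtype=np.uint8))
        )
        if self.bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("bits must be 0/1")

    def __len__(self) -> int:
        return int(self.bits.shape[0])

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def build_descriptor_bins(
    table: pd.DataFrame,
    n_bins: int = 5,
    strategy: str = "quantile",
) -> list[DescriptorBinSpec]:
    """Learn per-descriptor bin edges from a (training) descriptor table.

    Parameters
    ----------
    table
        Rows are items, columns are numeric descriptors.
    n_bins
        Total bins per descriptor (including the two open-ended outer
        bins); must be >= 3 so each spec has at least two edges.
    strategy
        ``"quantile"`` places the ``n_bins - 1`` edges at the interior
        quantiles (≈ equal counts per bin); ``"fixed"`` spaces them evenly
        across the training range.

    A constant column cannot support any cut and degrades to a flagged
    single-bin spec (with a warning).
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3 (each spec needs >= 2 edges)")
    if strategy not in ("quantile", "fixed"):
        raise ValueError(f"unknown binning strategy {strategy!r}")
    specs: list[DescriptorBinSpec] = []
    for col in table.columns:
        values = table[col]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() & values.notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric descriptor value at row {row!r}, column {col!r}"
            )
        if numeric.isna().any():
            row = numeric.isna().idxmax()
            raise ValueError(f"missing descriptor value at row {row!r}, column {col!r}")
        arr = numeric.to_numpy(dtype=float)
        n_distinct = len(np.unique(arr))
        if strategy == "quantile":
            if 1 < n_distinct < n_bins:
                raise ValueError(
                    f"column {col!r}: quantile binning needs >= {n_bins} distinct values"
                )
            if n_distinct == 1:
                edges = np.array([])
            else:
                qs = np.arange(1, n_bins) / n_bins
                edges = np.unique(np.quantile(arr, qs))
        else:
            lo, hi = float(arr.min()), float(arr.max())
            if hi > lo:
                edges = lo + (hi - lo) * np.arange(1, n_bins) / n_bins
            else:
                edges = np.array([])
        if len(edges) < 2:
            warnings.warn(
                f"column {col!r} is (nearly) constant; using a degenerate single bin",
                stacklevel=2,
            )
            specs.append(DescriptorBinSpec(col, (), degenerate=True))
        else:
            specs.append(DescriptorBinSpec(col, tuple(float(e) for e in edges)))
    return specs


def encode_sequence(seq: SequenceRecord, scheme: EncodingScheme) -> BinaryVector:
    """One-hot encode a sequence: bit (position p, symbol s) set iff seq[p] == s.

    The unknown residue ``X`` leaves its whole block zero (it matches
    nothing); positions beyond the sequence end are all zero.
    """
    if scheme.mode != "sequence":
        raise ValueError("encode_sequence needs a sequence-mode scheme")
    if len(seq) > scheme.max_length:
        raise ValueError(
            f"sequence {seq.id!r} length {len(seq)} exceeds scheme max_length "
            f"{scheme.max_length}"
        )
    bits = np.zeros(scheme.width, dtype=np.uint8)
    for p, ch in enumerate(seq.residues):
        if ch == UNKNOWN:
            continue
        bits[p * BLOCK + _SYMBOL_INDEX[ch]] = 1
    return BinaryVector(bits, scheme.scheme_id)


def decode_sequence(vec: BinaryVector, scheme: EncodingScheme) -> str:
    """Invert :func:`encode_sequence` (all-zero blocks decode to ``X``).

    Trailing all-zero blocks (padding beyond the original length) are
    stripped, so round-tripping an X-free sequence is exact.
    """
    if scheme.mode != "sequence":
        raise ValueError("decode_sequence needs a sequence-mode scheme")
    chars = []
    bits = vec.bits
    for p in range(scheme.max_length):
        block = bits[p * BLOCK : (p + 1) * BLOCK]
        hits = np.flatnonzero(block)
        if len(hits) == 0:
            chars.append(UNKNOWN)
        elif len(hits) == 1:
            chars.append(ALPHABET[hits[0]])
        else:
            raise ValueError(f"position {p}: more than one bit set")
    return "".join(chars).rstrip(UNKNOWN)


def encode_descriptors(
    row, bins: list[DescriptorBinSpec] | tuple[DescriptorBinSpec, ...]
) -> BinaryVector:
    """One-hot encode a descriptor row: exactly one bit set per block."""
    scheme = EncodingScheme("descriptor", bins=tuple(bins))
    bits = np.zeros(scheme.width, dtype=np.uint8)
    offset = 0
    for spec in bins:
        try:
            value = row[spec.descriptor_name]
        except (KeyError, IndexError):
            raise KeyError(
                f"row is missing descriptor {spec.descriptor_name!r}"
            ) from None
        value = float(value)
        if np.isnan(value):
            raise ValueError(f"descriptor {spec.descriptor_name!r} is NaN")
        bits[offset + spec.bin_index(value)] = 1
        offset += spec.n_bins
    return BinaryVector(bits, scheme.scheme_id)


def extract_frames(item, frame_length: int, step: int = 1) -> list[tuple[int, object]]:
    """Slice an item into overlapping frames (0-based, half-open windows).

    ``item`` may be a :class:`SequenceRecord`, a string, a
    :class:`BinaryVector` or any sliceable sequence. Returns
    ``[(start, segment), ...]`` with ``floor((n - L) / step) + 1`` frames;
    a frame longer than the item yields an empty list with a warning.
    """
    if frame_length < 1 or step < 1:
        raise ValueError("frame_length and step must be positive")
    if isinstance(item, SequenceRecord):
        data = item.residues
    elif isinstance(item, BinaryVector):
        data = item.bits
    else:
        data = item
    n = len(data)
    if frame_length > n:
        warnings.warn(
            f"frame_length {frame_length} exceeds item length {n}; no frames",
            stacklevel=2,
        )
        return []
    return [
        (start, data[start : start + frame_length])
        for start in range(0, n - frame_length + 1, step)
    ]


def _as_bits(v) -> np.ndarray:
    if isinstance(v, BinaryVector):
        return v.bits
    return np.asarray(v, dtype=np.uint8)


def tanimoto(a, b) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| of two fingerprints.

    Defined as 0.0 for two all-zero vectors.
    """
    if isinstance(a, BinaryVector) and isinstance(b, BinaryVector):
        if a.scheme_id != b.scheme_id:
            raise ValueError(
                f"scheme mismatch: {a.scheme_id!r} vs {b.scheme_id!r}"
            )
    ab, bb = _as_bits(a), _as_bits(b)
    if ab.shape != bb.shape:
        raise ValueError(f"width mismatch: {ab.shape[0]} vs {bb.shape[0]}")
    union = int(np.logical_or(ab, bb).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(ab, bb).sum()) / union


def diversity_fraction(vectors, cutoff: float = 0.7) -> float:
    """Fraction of fingerprints whose nearest neighbour is below ``cutoff``.

    For each vector the maximum Tanimoto similarity to any *other* vector
    is found; the returned value is the fraction of vectors for which that
    maximum is strictly below the cutoff — the conventional summary of
    chemical-library diversity.
    """
    if len(vectors) < 2:
        raise ValueError("diversity_fraction needs at least 2 vectors")
    mat = np.stack([_as_bits(v) for v in vectors]).astype(np.float64)
    inter = mat @ mat.T
    pops = mat.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(sim, -np.inf)
    nearest = sim.max(axis=1)
    return float(np.mean(nearest < cutoff))
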