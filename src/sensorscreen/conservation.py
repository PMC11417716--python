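"""MSA column conservation, positional thresholds, and segment selection.

For an alignment of k sequences, the conservation factor of residue type
i at column j is

    C_ij = (n_ij / k) * 100%,

where n_ij counts the sequences carrying residue i at column j. Gaps
count in the denominator k but are not a residue type, so a gappy column
can never look conserved. A positional conservation threshold (PCT)
flags a column as conserved when its best residue reaches the threshold;
maximal runs of flagged columns of at least ``min_run`` form the
segments recommended for comparative modeling.

Counts are kept as exact integers, so C_ij sums are exact in rational
arithmetic: per column, sum_i C_ij plus the gap percentage equals 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import AMINO_ACIDS, GAP, UNKNOWN, ALPHABET

__all__ = [
    "MsaMatrix",
    "ConservationProfile",
    "PctRule",
    "conservation_factor",
    "conservation_profile",
    "apply_pct",
    "select_conserved_segments",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class MsaMatrix:
    """k aligned sequences of m columns over the residue alphabet."""

    rows: tuple[str, ...]
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise ValueError("alignment needs at least one sequence")
        m = len(self.rows[0])
        if m == 0:
            raise ValueError("alignment rows must be non-empty")
        for r, row in enumerate(self.rows):
            if len(row) != m:
                raise ValueError(
                    f"ragged alignment: row {r} has length {len(row)}, expected {m}"
                )
            for c, ch in enumerate(row):
                if ch not in ALPHABET:
                    raise ValueError(
                        f"row {r}, column {c}: {ch!r} is not in the residue alphabet"
                    )
        if self.ids and len(self.ids) != len(self.rows):
            raise ValueError("ids must match the number of rows")

    @property
    def k(self) -> int:
        return len(self.rows)

    @property
    def m(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class ConservationProfile:
    """Exact residue counts per column plus the derived percentages.

    ``counts[i, j]`` is n_ij for the 20 amino acids (alphabetical order);
    ``gap_counts[j]`` counts gaps (unknown ``X`` is tallied with gaps as
    "not a residue"). Percentages are ``100 * n / k``.
    """

    counts: np.ndarray
    gap_counts: np.ndarray
    k: int
    m: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        object.__setattr__(
            self, "gap_counts", np.asarray(self.gap_counts, dtype=np.int64)
        )
        if self.counts.shape != (len(AMINO_ACIDS), self.m):
            raise ValueError("counts must be 20 x m")
        if self.gap_counts.shape != (self.m,):
            raise ValueError("gap_counts must have length m")

    @property
    def percent(self) -> np.ndarray:
        """C_ij as floats: 100 * n_ij / k, shape (20, m)."""
        return 100.0 * self.counts / self.k

    @property
    def gap_percent(self) -> np.ndarray:
        return 100.0 * self.gap_counts / self.k


def conservation_factor(msa: MsaMatrix, residue: str, column: int) -> float:
    """C_ij = 100 * (rows with residue i at column j) / k, in percent."""
    if residue not in _AA_INDEX:
        raise ValueError(f"{residue!r} is not one of the 20 amino acids")
    if not 0 <= column < msa.m:
        raise ValueError(f"column {column} out of range [0, {msa.m})")
    n = sum(1 for row in msa.rows if row[column] == residue)
    return 100.0 * n / msa.k


def conservation_profile(msa: MsaMatrix) -> ConservationProfile:
    """Full 20 x m conservation table with exact integer counts."""
    counts = np.zeros((len(AMINO_ACIDS), msa.m), dtype=np.int64)
    gaps = np.zeros(msa.m, dtype=np.int64)
    for row in msa.rows:
        for j, ch in enumerate(row):
            if ch in (GAP, UNKNOWN):
                gaps[j] += 1
            else:
                counts[_AA_INDEX[ch], j] += 1
    return ConservationProfile(counts, gaps, msa.k, msa.m)


@dataclass(frozen=True)
class PctRule:
    """Positional conservation threshold (percent) + minimum run length."""

    threshold: float = 70.0
    min_run: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 100:
            raise ValueError("threshold must be in (0, 100]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def apply_pct(profile: ConservationProfile, rule: PctRule):
    """Flag conserved columns and name each column's winning residue.

    Column j is conserved iff max_i C_ij >= threshold, gaps excluded
    from the max; the winner is the argmax residue (alphabetically first
    on ties). Returns ``(flags: bool array, winners: list of residue or
    None)``.
    """
    pct = profile.percent
    best = pct.max(axis=0)
    winners_idx = pct.argmax(axis=0)  # argmax -> first max -> alphabetical winner
    flags = best >= rule.threshold
    winners = [
        AMINO_ACIDS[winners_idx[j]] if best[j] > 0 else None for j in range(profile.m)
    ]
    return flags, winners


def select_conserved_segments(flags, rule: PctRule) -> list[tuple[int, int]]:
    """Maximal conserved runs of length >= min_run as 0-based half-open spans."""
    flags = np.asarray(flags, dtype=bool)
    segments = []
    start = None
    for j, f in enumerate(flags):
        if f and start is None:
            start = j
        elif not f and start is not None:
            if j - start >= rule.min_run:
                segments.append((start, j))
            start = None
    if start is not None and len(flags) - start >= rule.min_run:
        segments.append((start, len(flags)))
    return segments
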