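"""Seeded synthetic fixtures with known ground truth.

Every generator is a pure function of its parameters and seed, so tests
and command-line runs are exactly reproducible. The default scales
mirror the study designs the toolkit targets, downscaled 5-10x for
desk-scale runtimes: a four-class receptor-like set of 20 sequences per
class (vs. 167 real amine receptors), 60 active / 600 inactive
descriptor rows at the 1:10 imbalance of a 300/3000 hERG design, and
seven ordered helix-like motifs for the receptor battery.

These fixtures emulate class structure, motif placement, imbalance and
noise — not real protein evolution or chemically valid molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import MsaMatrix
from .encoding import AMINO_ACIDS, SequenceRecord
from .nucleation import check_helix_order

__all__ = [
    "FixtureSpec",
    "PlantedMotifData",
    "GpcrLikeData",
    "gen_planted_motif_sequences",
    "gen_gpcr_like",
    "gen_descriptor_dataset",
    "gen_toy_msa",
]

_DESCRIPTOR_NAMES = ["mw", "logp", "hbd", "hba", "tpsa", "rotb", "chi0", "arom"]


@dataclass(frozen=True)
class FixtureSpec:
    """Study-condition defaults shared by the generators.

    ``mutation_rate`` is the per-position probability that a planted
    motif residue is substituted (always to a different residue);
    ``effect_size`` is the active-class mean shift per descriptor in
    pooled-SD units.
    """

    seed: int = 0
    n_classes: int = 4
    n_per_class: int = 20
    length: int = 300
    motif_length: int = 15
    mutation_rate: float = 0.02
    n_active: int = 60
    n_inactive: int = 600
    n_descriptors: int = 5
    effect_size: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be a probability")
        for f in ("n_classes", "n_per_class", "length", "motif_length",
                  "n_active", "n_inactive", "n_descriptors"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)]


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> tuple[str, int]:
    """Substitute each position with prob ``rate`` to a *different* residue."""
    out = list(motif)
    n_mut = 0
    for p in range(len(out)):
        if rate > 0 and rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[p]]
            out[p] = choices[int(rng.integers(len(choices)))]
            n_mut += 1
    return "".join(out), n_mut


@dataclass(frozen=True)
class PlantedMotifData:
    records: tuple
    labels: dict
    placements: dict
    motifs: dict


def gen_planted_motif_sequences(
    n_classes: int = 4,
    n_per_class: int = 20,
    length: int = 300,
    motif_length: int = 15,
    mutation_rate: float = 0.02,
    seed: int = 0,
    start_range: tuple[int, int] | None = None,
    class_names=None,
) -> PlantedMotifData:
    """Multi-class sequences, each carrying its class's motif once.

    Each class gets a random motif; every sequence of the class carries
    it at a recorded start (uniform in ``start_range``, default the full
    feasible range), with per-position substitution noise; all other
    positions are i.i.d. uniform residues. Ground truth (labels, starts,
    motifs) is returned alongside the records.
    """
    if motif_length > length:
        raise ValueError("motif_length must not exceed sequence length")
    max_start = length - motif_length
    if start_range is None:
        start_range = (0, max_start)
    lo, hi = start_range
    if not (0 <= lo <= hi <= max_start):
        raise ValueError(
            f"start_range {start_range} infeasible for length {length}, "
            f"motif {motif_length}"
        )
    rng = np.random.default_rng(seed)
    if class_names is None:
        class_names = [f"class{c + 1}" for c in range(n_classes)]
    motifs = {
        cls: "".join(_random_sequence(rng, motif_length)) for cls in class_names
    }
    records, labels, placements = [], {}, {}
    for cls in class_names:
        for i in range(n_per_class):
            sid = f"{cls}_{i:03d}"
            residues = _random_sequence(rng, length)
            start = int(rng.integers(lo, hi + 1))
            planted, _ = _mutate(rng, motifs[cls], mutation_rate)
            residues[start : start + motif_length] = list(planted)
            records.append(SequenceRecord(sid, "".join(residues)))
            labels[sid] = cls
            placements[sid] = start
    return PlantedMotifData(tuple(records), labels, placements, motifs)


@dataclass(frozen=True)
class GpcrLikeData:
    positives: tuple
    negatives: tuple
    placements: dict
    motifs: tuple


def gen_gpcr_like(
    n_positives: int = 20,
    n_negatives: int = 20,
    length: int = 300,
    helix_length: int = 15,
    loop_range: tuple[int, int] = (15, 30),
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> GpcrLikeData:
    """Seven-helix receptor mimics plus composition-matched shuffles.

    Positives carry seven fixed motifs ("helices") in order, separated
    by loops of random length in ``loop_range``; negatives are
    residue-shuffled copies of positives (same composition, motifs
    destroyed). Ground-truth starts are strictly increasing by
    construction.
    """
    n_helices = 7
    lo, hi = loop_range
    if lo < 0 or hi < lo:
        raise ValueError("loop_range must be 0 <= lo <= hi")
    worst = n_helices * helix_length + (n_helices - 1) * hi
    if worst > length:
        raise ValueError(
            f"geometry infeasible: 7 helices of {helix_length} with loops up to "
            f"{hi} need up to {worst} residues but length is {length}"
        )
    rng = np.random.default_rng(seed)
    motifs = tuple(
        "".join(_random_sequence(rng, helix_length)) for _ in range(n_helices)
    )
    positives, placements = [], {}
    for i in range(n_positives):
        loops = [int(rng.integers(lo, hi + 1)) for _ in range(n_helices - 1)]
        used = n_helices * helix_length + sum(loops)
        offset = int(rng.integers(length - used + 1))
        residues = _random_sequence(rng, length)
        starts = []
        pos = offset
        for h in range(n_helices):
            planted, _ = _mutate(rng, motifs[h], mutation_rate)
            residues[pos : pos + helix_length] = list(planted)
            starts.append(pos)
            pos += helix_length + (loops[h] if h < n_helices - 1 else 0)
        sid = f"pos_{i:03d}"
        positives.append(SequenceRecord(sid, "".join(residues)))
        placements[sid] = starts
        assert check_helix_order(starts, min_gap=1)
    negatives = []
    for i in range(n_negatives):
        src = positives[i % len(positives)]
        letters = list(src.residues)
        rng.shuffle(letters)
        negatives.append(SequenceRecord(f"neg_{i:03d}", "".join(letters)))
    return GpcrLikeData(tuple(positives), tuple(negatives), placements, motifs)


def gen_descriptor_dataset(
    n_active: int = 60,
    n_inactive: int = 600,
    n_descriptors: int = 5,
    effect_size=2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Active/inactive descriptor table with class-shifted distributions.

    Inactive rows draw each descriptor from N(0, 1); active rows from
    N(effect, 1) with the per-descriptor ``effect_size`` (scalar or
    sequence, in pooled-SD units). Default 60:600 keeps the 1:10
    class imbalance of a 300-active / 3000-inactive screening design.
    Descriptor values are standardized surrogates for properties like
    molecular weight or logP; column names borrow those conventions.
    Returns ``(table indexed by molecule id, boolean labels)``.
    """
    if n_active < 1 or n_inactive < 1:
        raise ValueError("class counts must be positive")
    if n_descriptors < 2:
        raise ValueError("need at least 2 descriptors")
    effects = np.broadcast_to(
        np.asarray(effect_size, dtype=float), (n_descriptors,)
    ).copy()
    rng = np.random.default_rng(seed)
    names = [
        _DESCRIPTOR_NAMES[i] if i < len(_DESCRIPTOR_NAMES) else f"d{i + 1}"
        for i in range(n_descriptors)
    ]
    act = rng.normal(loc=effects, scale=1.0, size=(n_active, n_descriptors))
    inact = rng.normal(loc=0.0, scale=1.0, size=(n_inactive, n_descriptors))
    ids = [f"act_{i:04d}" for i in range(n_active)] + [
        f"inact_{i:04d}" for i in range(n_inactive)
    ]
    table = pd.DataFrame(np.vstack([act, inact]), index=ids, columns=names)
    table.index.name = "id"
    labels = pd.Series([True] * n_active + [False] * n_inactive, index=ids, name="active")
    return table, labels


def gen_toy_msa(
    k: int,
    m: int,
    conserved_columns: dict[int, str] | None = None,
    seed: int = 0,
    background: str = AMINO_ACIDS,
) -> MsaMatrix:
    """Toy alignment: chosen columns fixed to a residue, the rest i.i.d."""
    conserved_columns = conserved_columns or {}
    if len(conserved_columns) >= m:
        raise ValueError("conserved columns must be fewer than total columns")
    for j, res in conserved_columns.items():
        if not 0 <= j < m:
            raise ValueError(f"conserved column {j} out of range")
        if res not in AMINO_ACIDS:
            raise ValueError(f"{res!r} is not one of the 20 amino acids")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(k):
        row = [background[j] for j in rng.integers(len(background), size=m)]
        for j, res in conserved_columns.items():
            row[j] = res
        rows.append("".join(row))
    return MsaMatrix(tuple(rows), tuple(f"seq_{i:03d}" for i in range(k)))
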