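# Methods

This note documents the models, numerical choices and open design
decisions behind sensorscreen, and what the synthetic fixtures do and do
not demonstrate.

## Binary encoding

Items are one-hot encoded under a frozen scheme serialized with every
model. Sequence mode allots one 22-symbol block per position
(`ACDEFGHIKLMNPQRSTVWY` + gap `-` + unknown `X`, in that fixed order).
The unknown residue encodes as an all-zero block — it matches nothing,
rather than inventing similarity to any residue. Gaps are legal only in
aligned contexts; the plain FASTA reader rejects them so a gap can never
silently frame-shift window extraction. Coordinates are 0-based with
half-open windows throughout the API; reports intended for humans print
1-based inclusive ranges.

Descriptor mode allots one block per descriptor, one bit per bin. Bin
edges are learned on the training table only; by default five bins per
descriptor with edges at the four interior quantiles, so bins are
scale-free and roughly equally populated. The outermost bins are
open-ended, so a test-set value outside the training range still encodes
(into the lowest or highest bin) instead of failing. Because each spec
must carry at least two edges, the minimum is three bins; a constant
training column cannot support any cut and degrades to a flagged
single-bin block with a warning. The fixed-width strategy (evenly spaced
edges across the training range) is available when bins should carry
physical units, e.g. 65-dalton molecular-weight slabs.

## Sensor scoring

A sensor's TP-mode score of a segment is the weight-summed XNOR with its
pattern; TN mode is the weight-summed XOR. The two partition the total
weight exactly, which the tests assert to machine precision, so scoring
in TP mode alone loses no information: the negative-class evidence is
folded into the weights. Weights are per-bit log-odds (base 2) of
agreeing with the pattern in positive versus negative training segments,
smoothed with a pseudo-count of 0.5 on both frequencies; any positive
pseudo-count keeps weights finite even for bits that are perfectly
class-pure. The pattern itself is the per-bit majority of the positive
segments, ties set to 1.

Sliding sensors scan every window at a configurable bit stride and keep
the maximum (the best local match, consistent with selecting the highest
scoring segment during nucleation), with ties broken toward the smallest
start for determinism. Sequence sensors use a stride of 22 bits — the
per-position block width — so windows always align with residue
boundaries; a 1-bit stride would score frames that straddle blocks and
correspond to no residue window. Scanning is vectorized: XNOR against a
fixed pattern is affine in the segment, so all window scores reduce to
one matrix-vector product.

## Nucleation

Cores grow by exactly one window per step: train a sensor on the core
versus a negative window pool, scan all training sequences, absorb the
globally best window not already in the core (keyed by sequence id and
start). The stopping rule is validation-MCC patience (default 2): after
each step the fresh sensor scores a labeled validation set by best
window score, the MCC-optimal threshold is found exhaustively, and
iteration stops when the best MCC has not improved for `patience`
consecutive steps (or at `max_iter`, or when every window is absorbed).
The sensor returned is the one with the best recorded validation MCC,
not necessarily the last. The negative pool is sampled uniformly from
negative sequences, seeded, with roughly ten negative windows per
eventual core member; when no negative set exists, windows come from
residue-shuffled positives, which preserve composition while destroying
motifs. In the one-vs-rest trainer the training set itself serves as the
stopping-rule validation set; on the planted-motif fixtures this is
sufficient because the holdout is never touched.

For seven-helix receptors one sensor is nucleated per helix from its own
seed windows. The combined receptor score is the weighted sum of the
seven best matches; when the seven starts are not strictly increasing
with at least `min_gap` residues between them (default 15, a plausible
minimum loop length — configurable, not an empirical claim), a penalty
of 25% of the absolute sum is subtracted. A penalty rather than hard
rejection keeps early training stable when sensors are still inaccurate;
setting the penalty to 100% recovers hard rejection.

## Evaluation and optimization

Predictions use `score >= threshold` (boundary items are positive; this
convention changes confusion counts and is therefore fixed). MCC with
any zero denominator factor is defined as 0, keeping threshold
optimization total. Thresholds are optimized exhaustively over midpoints
between consecutive distinct scores plus sentinels beyond both extremes;
ties go to the lowest threshold. ROC AUC is the rank (Mann–Whitney)
statistic with half-credit ties. Per-sensor weights are tuned by
coordinate ascent over the discrete factor grid {0, 0.25, 0.5, 1, 2, 4},
re-optimizing the threshold at every trial; the objective is
non-decreasing over accepted moves and the procedure is deterministic
given input order. Continuous weight optimization is deliberately out of
scope — the factor grid matches the multiplicative-factor design.

Splits default to two-thirds training, stratified per class (a class
with fewer than two members stays in training). Repeated-holdout
validation draws per-class holdout counts each run (default one third of
each class), refits on the remainder, and applies the training-optimal
threshold to the holdout; three runs are averaged by default.

## Activity indexing

The 0–10 index is a min-max map of the raw score over the training score
range, clipped outside it. The scale anchors a conventional screening
threshold of 5.0 at the training mid-range; the simplest monotone map
was chosen because only the threshold convention, not a distributional
shape, is specified. The scale is serialized with the model, so indexing
is reproducible bit for bit.

## Hierarchical classification

Each hierarchy node holds one model per child label (one-vs-rest); an
item descends by per-node argmax with margin best-minus-second-best,
ties to the lexicographically smallest label, and abstains when the
margin falls below a configurable floor (default 0 = never abstain).

## MSA conservation

The conservation factor of residue i at column j is
`C_ij = 100 · n_ij / k`, with n_ij the count of sequences carrying i at
j and k the number of sequences. Gaps (and `X`) count in the denominator
but are not residue types, so per column the 20 residue percentages plus
the gap percentage sum to exactly 100 in rational arithmetic — the
profile stores integer counts so tests can verify this identity exactly.
A column is conserved when its best residue reaches the positional
conservation threshold (default 70%, configurable); conserved columns in
maximal runs of at least `min_run` (default 3) become the segments
recommended for comparative modeling. The per-column "vote" is realized
as argmax residue with threshold; alphabetical tie-break.

## Synthetic fixtures

Generators are pure functions of their parameters and seed (one RNG
threaded throughout, no global state). Defaults downscale the target
study designs 5–10× for desk-scale runtimes while preserving structure:
4 classes × 20 sequences of length 300 with length-15 motifs at 2%
per-position substitution (substitutions always change the residue, so
mutation counts are exactly binomial), 60 active / 600 inactive
descriptor rows at 1:10 imbalance with a 2-SD mean shift per descriptor,
and seven ordered helix motifs with 15–30 residue loops. Negatives for
the receptor fixture are residue-shuffled positives: composition-matched
but motif-free.

What passing these fixtures shows: the pipeline recovers planted signal
reliably — exact consensus recovery at zero noise, 100% holdout
assignment at 2% noise, near-ceiling AUC at 2-SD effects, null AUC near
0.5 at zero effect. What it does not show: performance on real protein
families (no phylogenetic correlation, no indels, no compositional bias
between classes) or real chemical libraries (descriptors are independent
Gaussians, not correlated physicochemical properties). Real-data
accuracy claims require real data.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
fixture scales above; the complete multi-class experiment (fixture
generation, four nucleation runs, holdout classification) takes on the
order of a second on one CPU thanks to the vectorized window scan.

## Known limitations

- Sensors are fixed-width and ungapped; an indel inside a motif breaks
  the frame.
- One-vs-rest scores from independently nucleated sensors are compared
  directly at the argmax step; no cross-class calibration is applied.
  On well-separated fixtures this is immaterial, on subtle real
  distinctions it may not be.
- The repeated-holdout MCC is sensitive to the training-set threshold at
  strong class imbalance; the reported means average over three draws.
- MCC reported for highly imbalanced designs can sit well below
  sensitivity/specificity intuition; the closed form is used throughout.
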