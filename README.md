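# sensorscreen

Virtual-sensor screening for protein sequences and molecular descriptor
tables: binary encoding, XNOR/XOR motif scoring, iterative nucleation,
MCC-driven optimization, hierarchical classification, 0–10 activity
indexing, and MSA conservation analysis.

## Who this is for

Computational biologists and cheminformaticians who need a transparent,
fully inspectable alternative to black-box classifiers for three kinds of
screening problems:

- **Protein family classification** — e.g. deciding whether a sequence is a
  G-protein-coupled receptor (GPCR) and which amine-receptor subfamily it
  belongs to, by detecting class-specific motifs and the ordered battery of
  seven transmembrane helices.
- **Ligand-based activity indexing** — e.g. flagging molecules likely to
  block the hERG potassium channel (a major source of drug-induced long QT
  syndrome) from cheap 1D/2D descriptors, on a 0–10 liability index.
- **Alignment post-processing** — selecting conserved segments of a
  multiple sequence alignment for comparative modeling.

## The model

Every item is encoded as a fixed-width binary vector: one 22-bit one-hot
block per sequence position (20 amino acids + gap + unknown), or one
one-hot block per binned molecular descriptor (e.g. a bit for "molecular
weight in 155–220 Da").

A **virtual sensor** is a window-length bit pattern `p` with per-bit
weights `w` (its *sensor weight score*, SWS, components). Against a
segment `s` it scores

    SWS_TP(s) = Σ_j w_j · XNOR(p_j, s_j)      (positive-class agreement)
    SWS_TN(s) = Σ_j w_j · XOR(p_j, s_j)       (negative-class disagreement)

which partition `Σ_j w_j` exactly. Weights are trained as per-bit base-2
log-odds of pattern agreement in positive versus negative example
segments, with pseudo-count smoothing; a sliding sensor reports the
best-scoring frame along the vector.

Sensors are grown by **nucleation**: starting from a small core of
exemplar windows (expert knowledge or planted ground truth), a sensor is
trained on the core, every training sequence is scanned, the single
highest-scoring unseen window is absorbed into the core, and the cycle
repeats until the validation Matthews correlation coefficient (MCC) stops
improving. Decision thresholds are chosen by exhaustive MCC maximization;
per-sensor weight factors by coordinate ascent over a discrete factor
grid. For seven-helix receptors, one sensor per helix is nucleated and a
sequence's combined score is the weighted sum of the seven best matches,
penalized when the helices are not found in the proper order. Activity
models map raw scores onto a 0–10 index by min-max scaling over the
training score range (so 5.0 is a natural screening threshold).

Everything is testable offline: the `simulate` module generates seeded
fixtures with known ground truth (planted motifs, seven-helix mimics,
class-shifted descriptor tables at 1:10 imbalance, toy alignments).

## Worked example

```python
from sensorscreen import gen_descriptor_dataset, train_descriptor_model, eli_index
from sensorscreen.experiments import multiclass_holdout_tp_rate, descriptor_validation_mcc

# 4-class receptor-like sequences, planted motifs, 2% noise:
# nucleate one-vs-rest sensors, classify the 1/3 holdout by argmax.
rate, n = multiclass_holdout_tp_rate(seed=17)
print(f"holdout TP rate: {rate:.1f}% (n={n})")

# 60 active / 600 inactive descriptor rows, effect size 2 SD:
table, labels = gen_descriptor_dataset(seed=0)
model = train_descriptor_model(table, labels.to_numpy(dtype=bool))
print(round(eli_index(model, table.iloc[0]), 2))            # an active molecule
print(round(eli_index(model, table.loc["inact_0000"]), 2))  # an inactive one

report, means = descriptor_validation_mcc(seed=0)
print({k: round(v, 3) for k, v in means.items()})
```

prints

```
holdout TP rate: 100.0% (n=28)
10.0
2.62
{'sensitivity': 0.933, 'specificity': 0.988, 'mcc': 0.901, 'auc': 0.977}
```

The 100% holdout rate shows the nucleation pipeline recovering all four
planted class motifs from a 2/3 training split; the activity model
separates the shifted active distribution almost perfectly (index 10.0
vs 2.6), and three leave-one-third-out runs average an MCC of 0.90 with
97.7% AUC on held-out molecules.

The same workflows are available from the shell:

```sh
sensorscreen simulate --kind descriptors --seed 3 --out-dir fix/
sensorscreen train --task activity --descriptors fix/descriptors.csv \
    --labels fix/labels.csv --out model.json
sensorscreen index --model model.json --input fix/descriptors.csv --out eli.csv
sensorscreen conserve --input alignment.fasta --threshold 70 --out-dir cons/
```

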