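# dhupred

Sequence-based prediction of dihydrouridine (D) modification sites in RNA.

Dihydrouridine is an abundant post-transcriptional tRNA modification found in
eukaryotes, bacteria and archaea, typically at conserved D-loop positions.
Experimental mapping of D sites is slow and laborious, so a practical
alternative is to classify candidate uridines directly from their sequence
context: a fixed-length window (41 nt) centred on the candidate U, labelled
positive (true D site) or negative (unmodified U). `dhupred` is a library for
building and stress-testing such predictors. It is aimed at computational
biologists who want a complete, reproducible pipeline — encoders, class
rebalancing, classifiers, metrics, cross-species evaluation — rather than a
single fitted model.

## What is inside

* **Window I/O** (`dhupred.seqio`) — labelled FASTA with `>id|species|label`
  headers, validation (length, alphabet, centre-U), per-species composition
  summaries. DNA-alphabet input is accepted (T→U).
* **Eleven encoders** (`dhupred.encoders`) — NCP (three chemistry bits per
  base: purine/pyrimidine ring, amino/keto functional group, weak/strong
  hydrogen bonding), BINARY one-hot, ENAC sliding-window composition,
  Kmer/RCKmer, NAC/DNC/TNC, ANF prefix densities, EIIP potentials and
  PseEIIP. For a 41-nt window the dimensions are 123, 164, 148, 4^k, 10/32,
  4, 16, 64, 41, 41 and 64 respectively.
* **Resampling** (`dhupred.resample`) — random or stratified train/test
  partitioning and the two-pass probabilistic oversampling rule: each
  positive *training* window is duplicated independently with probability
  p = 0.5 in each of two passes, after partitioning, never on the test side.
  Duplicates carry `#dup` provenance suffixes so leakage checks are
  mechanical.
* **Classifiers** (`dhupred.models`) — RF, SVM (RBF), KNN (k selected by
  inner CV from {1,3,5,7,9}), LR and MLP (one sigmoid hidden layer) behind
  one fit/score interface; scores are positive-class probabilities,
  thresholded at 0.5.
* **Evaluation** (`dhupred.evaluation`) — Sn = 1 − N₋₊/N₊,
  Sp = 1 − N₊₋/N₋, Acc, MCC, precision, F1, and trapezoid-rule ROC AUC
  (equal to the Mann–Whitney pair statistic); repeated stratified 5-fold
  cross-validation with fold-internal oversampling; leakage-guarded
  independent testing.
* **Experiments** (`dhupred.experiments`) — encoder × classifier grids with
  a shared split, the 30/20/10 % partition-rate study, and three
  cross-species designs: train-on-one-species, leave-one-species-out, and
  the full 5×5 accuracy matrix with within-species CV on the diagonal.
* **Synthetic benchmark** (`dhupred.synthetic`) — generates datasets shaped
  like the published five-species benchmark (550 windows, 176 positive /
  374 negative; S. cerevisiae 91/93, etc.) with a planted positional motif
  whose strength is a dial (`effect_size`), including a zero-signal null
  and an optional divergent species.

A thin CLI (`dhupred simulate|encode|train|predict|eval|benchmark|
crossspecies`) wraps the library for shell use; every command emits a
`runconfig.json` that replays the run bit-identically via `--config`.

## Worked example

`examples/03_train_evaluate.py` runs the best-performing configuration —
random forest on NCP features, 10 % independent test split, two-pass
oversampling — on synthetic benchmark-shaped data:

```
5-fold CV x5 (550 windows): AUC = 0.9667 +/- 0.0129, Acc = 0.8938
independent test (55 windows): Sn = 0.8889, Sp = 0.9730, Acc = 0.9455,
MCC = 0.8751, AUC = 0.9812
```

The CV line is the mean over 25 folds (5 folds × 5 repeats) on all 550
windows; the independent line scores the 55 held-out windows never seen in
training or oversampling. Sn and Sp are the recall of positives and
negatives, MCC the correlation between predicted and true labels, AUC the
threshold-free ranking quality (0.5 = chance). The other examples cover
dataset simulation (`01`), the encoders (`02`) and the three cross-species
experiments (`04`).

Real benchmark data can be used by converting its FASTA headers to the
`>id|species|label` convention (any delimiter, `read_fasta(..., delimiter=)`)
— the windows themselves need no transformation.

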