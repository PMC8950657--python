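# Methods

This note records the scientific model behind `dhupred`, the parameter
choices that matter, what the synthetic benchmark does and does not emulate,
and the numerical conventions adopted where the design was genuinely open.

## Problem and model

A candidate dihydrouridine site is represented by a fixed-length RNA window
(default 41 nt, odd so a unique centre exists) centred on the candidate U.
Prediction is binary classification of windows: positive = true D site,
negative = unmodified U. The pipeline is

1. partition the labelled windows into training and test sets (default test
   fraction 0.10, the rate that performed best in the partition-rate study
   this package reproduces; 0.30 and 0.20 are the other study points);
2. oversample the positive *training* windows: two independent passes, each
   duplicating every positive with probability 0.5 — in expectation the
   positive count doubles, and the added-duplicate count is
   Binomial(2·n⁺, 0.5). Duplication happens strictly after partitioning and
   never touches the test side;
3. encode both sides with one of eleven feature schemes;
4. fit one of five classifiers;
5. evaluate with Sn, Sp, Acc, MCC, precision, F1 and ROC AUC, via repeated
   stratified 5-fold cross-validation (5 repeats) and an independent test.

All encoders are sample-local (no training-set statistics), so encoding
before or after the split is mathematically equivalent; the pipeline still
encodes after splitting so the no-leakage argument is structural rather than
statistical. Every experiment additionally runs a mechanical check that no
test id — including the ancestral id of any oversampling duplicate — occurs
in its training set.

## Encoders

| scheme | idea | dim (41 nt) |
|---|---|---|
| NCP | 3 chemistry bits per base | 123 |
| BINARY | one-hot per base, order A,G,C,U | 164 |
| ENAC | window-w base frequencies, step 1 (w = 5) | 148 |
| Kmer | k-mer frequencies, lexicographic A<C<G<U | 4^k |
| RCKmer | Kmer pooled by reverse complement (A↔U, C↔G) | 10 (k=2), 32 (k=3) |
| NAC/DNC/TNC | Kmer at k = 1/2/3 | 4/16/64 |
| ANF | prefix density of the base at each position | 41 |
| EIIP | per-base electron-ion interaction potential | 41 |
| PseEIIP | trinucleotide frequency × summed EIIP | 64 |

Conventions that required a decision:

* **NCP codes** follow the chemistry groupings — purine {G,A}, amino {C,A},
  weak H-bond {U,A} — giving A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1),
  the assignment used throughout the NCP literature.
* **BINARY** uses the explicit listing order A,G,C,U with C=(0,0,1,0);
  one-hot distinctness is mandatory, and the worked encoding of "GAGACU"
  (01001000…0001) is consistent with it.
* **Kmer denominator**: the default `kmer_count` mode divides occurrence
  counts by the number of k-mer positions L−k+1, so frequencies sum to 1
  (the behaviour of the standard encoder toolkits in this field); a
  `seq_length` mode dividing by L is retained for the alternative
  composition convention. Default k = 3, matching toolkit defaults.
* **ENAC** slides with step 1 and default window 5; each 4-block of the
  output is a probability vector.
* **EIIP constants** A=0.1260, C=0.1340, G=0.0806, U=0.1335 (U inherits the
  thymine value), kept in one editable table.
* **RCKmer** canonicalisation takes the lexicographic minimum of a k-mer and
  its RNA reverse complement; 2-mers collapse to 10 classes (4
  self-complementary + 6 pairs), odd k has no self-complementary k-mers, so
  3-mers collapse to exactly 32.

## Classifiers

Unstated hyperparameters are fixed to documented defaults, all overridable
through `ModelSpec.hyperparams`: RF 100 trees, Gini, √d features per split;
SVM RBF with library-default C and gamma, probability calibration for
scores; KNN neighbour count chosen from {1,3,5,7,9} by stratified inner CV
on the training data only (skipped when a class is too small to fold or the
user pins `n_neighbors`); LR with L2 at default strength, threshold 0.5;
MLP one hidden layer of 100 logistic units (capped at 300 iterations —
runs are deterministic given the seed, and occasional non-convergence on
hard data is accepted rather than warned about). Class weights are uniform:
imbalance is the oversampling rule's job, not the loss function's.

## Evaluation

Sn, Sp and Acc are implemented as the error-rate forms
(1 − N₋₊/N₊ etc.); MCC as the classical count form. A property test holds
the two algebraic routes to each other at 1e−12 across random confusion
tables, which guards against misreading either formulation. Zero
denominators in MCC or precision return 0 with a logged warning; Sn/Sp with
an absent class raise instead, since no convention is defensible there.

AUC is the trapezoid integral of the empirical ROC curve (thresholds swept
over the observed scores); with tied scores grouped per threshold this
equals the Mann–Whitney statistic with ties counted ½, and a pair-counting
oracle enforces the identity in tests. CV folds are stratified by class by
default because unstratified folds can lose a class entirely at the
benchmark's smallest species sizes; repeats use seeds `seed + r` and are
recorded, with fold assignments, in the result object for replay.

## Synthetic benchmark

The generator emulates the composition of the published five-species
benchmark exactly: 550 windows of 41 nt, 176 positive / 374 negative, per
species (pos/neg) H.sapiens 29/68, M.musculus 13/48, D.melanogaster 9/38,
S.cerevisiae 91/93, E.coli 34/127. Every window has U at the centre.
Negatives are i.i.d. draws from the background composition (uniform by
default, configurable to skewed for composition-encoder stress tests).
Positives plant a position-specific motif on the ten positions flanking the
centre (offsets ±1..±5): at each motif position the preferred base gains
log-odds `effect_size` over the background (softmax), so

* `effect_size = 0` makes the positive and negative generative
  distributions identical — a null dataset on which any cross-validated AUC
  should sit within noise of 0.5;
* the reference strong value `effect_size = 2.0` (preferred-base
  probability ≈ 0.71 against a 0.25 background) yields RF+NCP CV AUC above
  0.95 on the 550-window default.

A positional motif was chosen over a compositional one because it exercises
both encoder families: position-aware schemes (NCP/BINARY/ENAC) see it
directly, composition schemes (Kmer family) through the induced base-usage
shift. An optional `divergent_species` draws its positives from an
unrelated motif, planting a cross-species generalization failure that the
5×5 experiment must surface (lowest off-diagonal row and column means).

What the generator does **not** emulate: real tRNA secondary structure, the
conserved D-loop context, sequence redundancy structure, or any
species-specific base composition. Passing tests on synthetic data
therefore certify the pipeline's correctness and its ability to recover a
planted signal at benchmark scale — not the absolute accuracies attainable
on real data, which depend on the true motif strength and are expected to
differ.

## Experiment designs

* **Grid benchmark**: one shared split across all encoder × classifier
  cells so differences are attributable to the pair, not the partition.
* **Partition-rate study**: rates 0.30/0.20/0.10 under a common seed
  policy. No monotonicity in the rate is asserted: that smaller test
  fractions helped is an empirical observation, not a law.
* **Experiment I**: train on S. cerevisiae (the largest species, about a
  third of the data), CV within it, independent test on the pooled rest.
* **Experiment II**: leave-one-species-out.
* **Experiment III**: all 25 ordered species pairs; the diagonal is
  within-species stratified 5-fold CV accuracy. A species whose smaller
  class cannot support 5 folds (D. melanogaster has 9 positives at
  benchmark composition) has k reduced to that class size with a logged
  warning rather than failing.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at the benchmark's native
scale (550 windows) for the headline pipeline checks, 200-sample datasets
for grid smoke tests, and 225-sample five-species datasets (45 per
species) for the cross-species harness — the smallest sizes at which every
species supports stratified 5-fold CV. Partition sizes use the floor rule
(|test| = ⌊rate·n⌋, remainder to training); stratified partitioning
allocates per-class test counts by largest remainder, keeping the exact
total while deviating at most one sample per class. Random streams for
partitioning, oversampling, model seeding and CV shuffling are seeded
independently so any one can be varied alone; the CLI expands a single
`--seed` into these component seeds deterministically.

## Known limitations

* Scores from the SVM backend come from internal Platt calibration, so its
  0.5-threshold labels can differ marginally from the uncalibrated
  decision boundary.
* The KNN inner selection refits the final model on the full training set
  with the chosen k, as is standard; the selected k is not exposed in the
  result objects.
* Published accuracies of comparable tools on the real benchmark are not
  reproducible here without the external data and their unstated splits
  and hyperparameters; this package reports its own measured numbers only.
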