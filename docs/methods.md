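# Methods

## Problem and data model

A KASP assay on a 96-well motherboard yields 94 DNA wells and 2 no-template
controls, each reporting a relative HEX signal *x* and relative FAM signal
*y*.  Typing quality is graded on an 11-level rubric (scores 0–100 in steps
of 10) describing the scatter geometry: cluster independence, homozygotes at
the axis extremes, the heterozygote cloud at the midpoint of the line
joining them, axis shifts, origin-ward tails, diffusion, and NTC behaviour.

A plate becomes a 192-value feature vector: interleaved (x, y) per well, DNA
wells first in plate order, NTC wells in positions 95–96.  The interleaved
layout keeps each well's two channels adjacent; a block layout (all x then
all y) would carry the same information and can be assembled from the same
records if needed.  Features are used unscaled by default — relative
fluorescence values already share a scale (≈0.3–1.4) — with an optional
standardization helper.

Labelled datasets split 84 % / 16 % by default, stratified by score (small
test sets are unstable for rare classes otherwise), train size rounded
half-up on fractional counts.

## Synthetic plate simulator

The simulator realizes each rubric class generatively so the pipeline can be
trained and validated with no proprietary data:

* Signal scale: background level 0.33, saturated level 1.30 on both
  channels, matching the magnitudes seen in real relative-fluorescence
  readouts; configurable.
* Clusters are isotropic Gaussians (sd 0.03 for clean classes) around
  class-specific centroids; homozygote composition defaults to
  40 AA / 40 BB / 14 AB (real genotype frequencies vary by population and
  are not modelled).
* Rubric clauses map to parameters: perpendicular heterozygote offset
  (score 90), along-line shift (80), one- vs both-homozygote axis shifts
  (70 / 60, with a trailing alternative for 70), exponential origin-ward
  tails on a 35 % tail fraction (50), diffusion multipliers 2.5 / 4 / 6 / 10
  (40 / 30 / 20 / 0), and NTC wells displaced into the signal range (10).
* Per-plate class variation: each continuous spec parameter is jittered
  uniformly within ±20 % of its class default (diffusion jittered on its
  excess over 1 so it never drops below the no-diffusion floor).
* All randomness flows from one `numpy` Generator; dataset generation is
  byte-reproducible for a fixed seed.

Geometric descriptors quantify the rubric clauses for verification:
within-cluster RMS spread, heterozygote-midpoint deviation decomposed
parallel/perpendicular to the homozygote line, tailing skewness of
projections onto the centroid→origin direction, a separation index (min
inter-centroid distance / mean spread), and an NTC specificity index (max
NTC distance from the background point (0.33, 0.33), relative to the mean
cluster distance from background; values above 0.5 flag an amplified
control).  Deviation components are signed along u = unit(hom_B − hom_A);
under the AA↔BB relabelling combined with the (x, y) reflection the parallel
component flips sign, so only magnitudes are symmetry-invariant.

What the simulator does **not** emulate: PCR chemistry and cycle-dependent
amplification, batch effects across plates, instrument-specific artefacts,
or the empirical score distribution of any real programme (class balance
defaults to uniform).  Tests passing on synthetic plates therefore show the
pipeline is sound on geometry-faithful data, not that any particular
accuracy transfers to a given real assay population.

## Hyperparameter search

Three maximizers over a shared space abstraction (integer/real/categorical
parameters, linear or log scale), each seeded and recording every
evaluation:

* random search — independent uniform draws (log-uniform on log scales);
* particle swarm — canonical update v ← 0.72·v + 1.49·r₁·(pbest − x) +
  1.49·r₂·(gbest − x) in the unit-cube embedding, positions clipped to
  bounds, zero initial velocities (standard constriction constants);
* Bayesian optimization — Matérn-5/2 Gaussian-process surrogate
  (scikit-learn's GP regression), expected-improvement acquisition maximized
  over 512 uniform candidates per round, random-proposal fallback if the
  surrogate fit fails.

The objective convention is mean 5-fold stratified-CV accuracy with folds
fixed per tuning run, ties broken by first-found.  The canonical pairing is
random search for the forest, PSO for the SVM, Bayesian optimization for
XGBoost.  Default spaces bracket the tuned default configurations
(RF 202 trees / depth 34, SVM C 695.65 / γ 0.0089, XGBoost 139 trees /
depth 7 / lr 0.29 etc.), so those configurations are always reachable.
Integer parameters are rounded from the continuous position at evaluation
time.  The SVM tuning objective skips Platt calibration (class predictions
do not depend on it); the final model is fitted with pairwise-coupled
sigmoid calibration because soft voting needs probabilities.

## Stacking

Five-fold out-of-fold construction: the training set is randomly partitioned
into five near-equal folds; each base learner (tuned SVM, tuned RF) is
fitted on four folds and predicts class probabilities on the fifth; blocks
are spliced into Z (22 columns for 11 classes).  Probabilities rather than
hard labels are used as meta-features — they preserve ranking information
and keep the meta-input low-dimensional (22 ≪ 192).  The XGBoost
meta-learner is tuned and fitted on (Z, y); base learners are then refitted
on the full training set for inference.  Hyperparameters are tuned once on
the full training set before the out-of-fold pass, not nested per fold —
cheaper, and the optimistic bias affects only tuning, not the meta-feature
hygiene (every Z row still comes from models that never saw that sample).
Classes absent from a fold's training data receive probability exactly 0.

The forest's absolute-majority decision rule (emit a class only if it takes
more than half of all tree votes, otherwise reject) is implemented and
tested as a standalone operation; inside stacking the forest contributes
vote fractions, since a meta-learner cannot consume a reject token.

## Neural branches

Both branches run on the package's reverse-mode autodiff engine (numpy
tensors, broadcasting ops, batched matmul, fused stable softmax, layer
norm, inverted dropout, Adam with global-norm gradient clipping at 5).
Training is full-precision float32 and bit-reproducible under a seed.

* **ANN-LSTM**: dense 192→128 + ReLU; the embedding enters a 128-unit LSTM
  as a length-1 sequence (the most literal reading of "adjust the shape of
  the output"); a 96-step (x, y)-per-well sequence mode is available behind
  `sequence_mode="wells"`.  Output layer maps the final hidden state to 11
  logits.  Defaults: lr 0.01, 500 epochs, batch 32, cross-entropy, Adam.
* **Transformer**: 96 tokens × 2 channels embedded to d_model 48 (divisible
  by nhead 6; a single 192-wide token would make self-attention degenerate
  over length 1), 3 encoder layers with dropout 0.01, feed-forward width 96,
  mean pooling, no positional encoding by default (wells are an unordered
  set).  Defaults: lr 0.001, 500 epochs, batch 32.
* Inputs are standardized per feature inside the model (statistics frozen at
  fit time): the raw all-positive features share a strong common mean that
  saturates the gated/attention nonlinearities at the default learning
  rates; standardization makes both branches train stably at lr 0.01/0.001.
* No early stopping or validation monitoring — a fixed epoch count.
  Dropout is active only in training mode; two inference passes are
  identical.

## Soft-voting fusion

Fused probabilities are the weight-normalized average of the three branches'
probability matrices; normalization keeps the output row-stochastic, and
the argmax is invariant to rescaling all weights.  Weights live on the
{0, 0.05, …, 1}³ lattice and are chosen by exhaustive search maximizing
argmax accuracy on an internal 15 % stratified validation split (ties break
to the lexicographically earliest point, which prefers sparse/small
weights).  After the search the branches are refitted on the full training
set by default (`refit=False` skips this for speed).  The final score is
10 × argmax class.

## Benchmark protocol and problem sizes

`run_benchmark` compares ten variants — tuned RF / SVM / XGBoost, ANN-LSTM,
Transformer, stacking, and the four soft-vote combinations — on one
synthetic dataset: 11 classes × 130 plates, split 100 train / 30 test per
class.  A 15 % validation carve from the training split serves the weight
grid searches; every model trains on the remaining fit portion, and all
vote combinations reuse the single-branch probability matrices, so each
branch is trained exactly once per run.  Component seeds derive from the one
root seed via `numpy.random.SeedSequence`.

Desk-scale parameter choices for the default benchmark: tuning budgets
4 / 8 / 6 evaluations (RF / SVM / XGBoost), ANN-LSTM 150 epochs and
Transformer 15 epochs at batch 64.  These are deliberate scaled-down
settings chosen to keep a full run in the minutes range on one CPU while
leaving every model clearly above chance and the fusion competitive with the
best single branch; the library defaults (500 epochs, larger budgets)
remain available through the config objects.

## Evaluation

Confusion-matrix metrics follow the standard per-class definitions with
macro averaging over classes present in the truth; classes with zero
denominators contribute 0 (logged).  The ratio TP/(TP+FP+FN) — a per-class
Jaccard-like quantity — is reported under its own name alongside
conventional overall accuracy (trace/total); the two are distinct statistics
and both are exposed.  Cohen's kappa uses p_o = trace/total and
p_e = Σ row·col / total², with the conventional six agreement bands
(0.81–1.00 almost perfect, …, < 0 none).  Per-class kappas collapse to
binary one-vs-rest before applying the same formula; classes absent from
both truth and prediction are reported as absent.  One-vs-rest AUC uses the
Mann–Whitney rank statistic with ties counted half, macro-averaged over
classes present; it equals exhaustive pair counting (property-tested).
Score-scale outputs are per-sample |Δscore| vectors and 11-band histograms.

## Known limitations

* Synthetic-only validation: no claim transfers automatically to real assay
  data (see the simulator's non-goals above).
* The GP surrogate operates in the unit cube with a fixed kernel; it is a
  capable small-budget optimizer, not a tuned AutoML component.
* The numpy autodiff engine is single-threaded and allocation-bound; it is
  sized for hundreds-to-thousands of plates, not large-scale training.
* Stacking meta-features from refit-on-full-train base models can be
  slightly sharper than the out-of-fold rows the meta-learner saw, which
  occasionally produces boundary misclassifications on atypical plates.
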