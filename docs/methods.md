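# Methods

## Problem and model

Quorum-sensing peptides (QSPs) are short bacterial autoinducers that trigger
density-dependent gene regulation; recognizing them from sequence alone is a
binary classification task (QSP = +1, Non-QSP = −1). The predictor here
follows the physicochemical-property (PCP) approach: a peptide of length L is
encoded into one value per amino-acid property scale — the arithmetic mean of
the scale's residue values over the sequence — giving a fixed-length,
length-independent feature vector (531 features when the full AAindex
database is supplied, 18 with the bundled informative subset). An RBF-kernel
SVM is trained on standardized features; a genetic algorithm with a
self-assessment report (GA-SAR) selects a small informative feature subset
jointly with the SVM hyperparameters; a random forest over the selected
features yields interpretable if–then rules and Gini-based importance
rankings.

The mean-over-residues encoding deserves a note: per-property averaging is
the only encoding that puts peptides of different lengths into a common
feature space, which a single SVM over variable-length peptides requires. It
is permutation-invariant within a sequence, so all positional information is
deliberately discarded (terminal-region count matrices recover it
descriptively, not predictively).

## Standardization

Feature columns are z-scored with mean and standard deviation (sample
convention, n−1) fitted on the training split only; independent/test data are
transformed with the training parameters and never refitted. The bundled
IR-QSP rule thresholds (range ≈ −0.9 to 1.4, centered near zero) are
interpreted on this standardized scale — raw property means would live on
arbitrary per-scale ranges, where such thresholds are implausible. Constant
columns raise an error naming the feature rather than silently producing
NaNs. Raw scale values are *not* pre-normalized before averaging; only the
final feature columns are standardized.

## SVM and probability outputs

The classifier is `sklearn.svm.SVC` with the RBF kernel. C and γ are tuned
over the power-of-two grid 2^−8, 2^−6, …, 2^8 for both parameters (exponent
step 2; 81 pairs) by mean stratified 10-fold cross-validation accuracy on one
fixed fold partition; exact ties resolve to smaller C, then smaller γ
(parsimony). Rows are canonically ordered by sample identifier before fold
assignment so input order cannot change results.

Class probabilities come from an explicit Platt layer (`PlattSVM`): a
logistic regression on decision values that were cross-validated within the
training set (stratified 5-fold), so the sigmoid never sees decisions of a
model trained on the same points. Two numerical details matter at strong
regularization (small C), where margins shrink toward zero:

* decision values are **centered per calibration fold** — the SVM bias term
  jitters across folds by more than the margin itself and would otherwise
  drown the signal when pooled;
* decision values are **scale-normalized** before the sigmoid fit, keeping
  the logistic optimization well-conditioned regardless of margin size.

The final kernel machine is refit on the full training data and its decision
values pass through the same centering/scaling. P(QSP) + P(Non-QSP) = 1 per
sample; the hard label is the probability argmax.

## Evaluation

Metrics are accuracy, sensitivity, specificity, the Matthews correlation
coefficient (MCC; defined as 0 when its denominator vanishes, flagged by the
degenerate confusion matrix itself), and the trapezoidal AUC, which equals
the normalized Mann–Whitney statistic with cross-class ties counting one
half. Because a single random benchmark/independent split can flatter a
model by chance, `repeated_rounds` re-draws stratified splits from a labeled
pool over independent rounds (default 10) and reports every metric as
mean ± SD; the scaler and all model selection are refit inside each round's
benchmark only.

## GA-SAR feature selection

Chromosomes carry a binary mask over candidate features plus two integer
exponent genes (c, g ∈ [−8, 8]) encoding C = 2^c and γ = 2^g. Storing
exponents as integers rather than 4-bit strings keeps all 17 grid points
(4 bits encode only 16; the integer gene resolves that mismatch without
losing a value). Fitness is mean 10-fold CV accuracy of the chromosome's SVM
on its masked columns; one fold partition per run (derived from the run
seed) makes fitnesses comparable across chromosomes, and evaluations are
memoized.

The self-assessment report scores each feature once before evolution:

    usefulness_j = minmax( |corr(x_j, y)| − mean_{k≠j} |corr(x_j, x_k)| )

— the relevance-minus-redundancy principle; the exact formula is this
package's choice. Mutation is biased by the profile: one deletion attempt
(probability ∝ 1 − usefulness among selected features), one addition attempt
(∝ usefulness among unselected), then repair of the selected count into
[m_min, m_max] = [5, 20] by further biased deletions/additions; exponent
genes move ±1 with probability 0.1, clipped to the range. Selection is
tournament of size 2 (ties prefer fewer features, then smaller C), crossover
is 20-point on the mask with the exponent pair inherited atomically per
child, and elitism of 1 makes the best-fitness history non-decreasing.
Defaults: 50 chromosomes, 50 generations.

## Rule extraction and the rule engine

Candidate rules are the root-to-leaf paths of a 100-tree
`RandomForestClassifier` (only the tree count is pinned; depth and
features-per-split follow library defaults and are exposed). Each path is
greedily pruned — a condition is dropped whenever dropping it does not
increase the rule's training misclassification count — deduplicated, and
ranked by accuracy, then cover, then brevity. Rule statistics (cover,
misclassified, accuracy %) are always recomputed by scanning the labeled
matrix, so extraction and evaluation cannot drift apart. The engine is a
disjunction of conjunctions: a query is positive when it satisfies every
condition of at least one positive rule; the default when nothing fires is
negative, the conservative choice for a screening task. "≤" is inclusive
and ">" exclusive, exactly as printed in the bundled rule set.

## Importance and composition analysis

Mean decrease of Gini index (MDGI) is the per-feature impurity reduction
summed within each tree, averaged over trees, reported in training-sample
units (the scale of R randomForest's `MeanDecreaseGini`); only relative
magnitudes and ranks carry meaning. To de-noise the ranking, importance is
averaged over 100 forests of 500 trees built with mtry = 1…100; mtry values
beyond the feature count are clamped to it, preserving the 100-model average
for small feature spaces.

Composition comparison tests each residue's per-sequence fraction between
classes with Welch's unequal-variance t-test (two-sided); the test choice is
this package's (a rank-sum alternative is exposed), since per-sequence
fractions have length-dependent variances that an equal-variance test would
ignore. Terminal count matrices index C-terminal positions from the terminus
inward (position 1 = last residue), matching terminal-region logo
conventions.

## Synthetic data

Two generators make every component testable without downloads; both are
pure functions of (spec, seed).

* **Composition peptides** — residues i.i.d. from a class-specific
  20-probability model, lengths uniform on [5, 30] (short signaling
  peptides; the bound is this package's choice). The default class models
  are the published QSP and Non-QSP residue frequencies, so synthetic sets
  reproduce the real compositional contrast (Phe enriched in positives, Lys
  depleted). What they do **not** model: positional structure, terminal
  motifs, phylogenetic redundancy, or any within-sequence correlation — so
  passing tests demonstrate the machinery and the compositional signal, not
  field performance on real peptides. (An optional terminal-enrichment mode
  was considered and dropped: the terminal-count operations are fully
  testable on i.i.d. sequences.)
* **Planted matrices** — standard-normal noise features; each informative
  feature's class means sit at ±δ/2 (δ = separation in SD units, default 2);
  optional redundancy copies add N(0, 0.1) jitter. Ground truth is returned
  so selection/importance recovery is scored exactly.

## Problem sizes used by the test suite and acceptance script

Chosen so the full pipeline exercises every component at meaningful signal
strength:

* GA-SAR recovery: 100 features, 6 informative, δ = 2, n = 400, 10 runs;
  population 24 × 12 generations (the SAR bias makes recovery fast, so the
  full 50 × 50 schedule is unnecessary for this check — it remains the
  library default).
* MDGI ranking: 20 features, 1 informative, δ = 2, n = 400, 10 runs;
  100 forests × 50 trees per run (500-tree forests remain the default).
* Repeated evaluation: pool 220 + 220 composition peptides, benchmark
  200/class, independent 20/class, 5 rounds in the acceptance script.
* Null checks: 30 noise features, n = 200, permuted labels.

## Known limitations

* The bundled 18-scale file carries the real accessions and descriptions of
  the informative property set but **synthetic** per-residue values (the
  AAindex database is not redistributed); predictions from the bundled
  fixture are for demonstration and testing. Supply a real AAindex-1 file
  for scientific use.
* The bundled rule set contains the eight positive (QSP) rules; the
  companion negative-class rules are not available and the engine's default
  class covers their role conservatively.
* Platt probabilities are calibrated within the training set; on very small
  training sets (tens of samples) they are coarse.
* MDGI values depend on forest randomness and sample size; compare ranks,
  not absolute values, across datasets.
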