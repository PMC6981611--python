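# iqsp

Sequence-based prediction and analysis of quorum-sensing peptides (QSPs) —
the short autoinducing peptides Gram-positive bacteria secrete to coordinate
density-dependent behavior (biofilm formation, virulence, competence).
Distinguishing QSPs from other short peptides matters for anti-virulence drug
discovery, and doing it from sequence alone makes large-scale screening
possible. This package is for computational biologists who want either a
ready predictor (FASTA in, predictions out) or the building blocks: property
encoding, wrapper feature selection, evaluation, and interpretable rules.

## The method

A peptide of length *L* over the 20 standard residues is encoded into one
feature per amino-acid property scale (AAindex):

    x_p = (1/L) · Σ_i  p(s_i)

the mean of scale *p* over the residues — a fixed-length vector regardless of
peptide length. Features are z-scored with training-set parameters, and an
RBF-kernel SVM classifies with C and γ tuned over the grid
{2⁻⁸, 2⁻⁶, …, 2⁸} × {2⁻⁸, 2⁻⁶, …, 2⁸} by stratified 10-fold
cross-validation. Around the SVM:

* **GA-SAR** (`iqsp.gasar`) — a genetic algorithm whose chromosomes hold a
  feature mask plus the SVM hyperparameter exponents. A precomputed
  *self-assessment report* scores each feature by
  minmax(|corr(x_j, y)| − mean_{k≠j}|corr(x_j, x_k)|) and biases mutation:
  useless features get deleted, useful ones get added, with the subset size
  repaired into [5, 20].
* **Evaluation** (`iqsp.svm_model`) — accuracy, sensitivity, specificity,
  MCC and AUC, reported as mean ± SD over repeated random
  benchmark/independent splits rather than a single lucky split.
* **IR-QSP rules** (`iqsp.ruleforest`) — if–then rules harvested from the
  decision paths of a 100-tree random forest, pruned and ranked; a peptide is
  called QSP when it satisfies every condition of at least one positive
  rule. The published 8-rule set ships as `irqsp_rules.tsv` (thresholds on
  the standardized feature scale).
* **Importance** (`iqsp.importance`) — mean-decrease-Gini feature importance
  averaged over 100 forests, per-residue composition contrasts with Welch
  tests, and terminal-region count matrices.
* **Synthetic data** (`iqsp.synthetic`) — composition-model peptide sets
  (defaults = the published QSP / Non-QSP residue frequencies) and
  planted-feature Gaussian matrices with known ground truth.

Note on bundled data: the 18-scale AAindex fixture carries the real
accessions and descriptions of the informative property set but *synthetic*
per-residue values (the database itself is not redistributed). Supply your
own AAindex-1 flat file for scientific use; the parser filters records with
NA values automatically.

## Worked example

```sh
$ iqsp generate --n-pos 60 --n-neg 60 --seed 7 --out-prefix demo
$ iqsp train --data demo.tsv --out model --seed 7
seed=7 config_hash=7607a7adef67 C=256 gamma=0.00390625 -> model
$ printf '>pep1\nFWFANKLFSYGG\n>pep2\nKKLLAAGGMKKL\n>pep3\nWNSFDFTGYKNF\n' > queries.fasta
$ iqsp predict queries.fasta --model model --rules
index  label  P(Non-QSP)  P(QSP)  fired_rules
1  QSP  0.0329  0.9671  8
2  Non-QSP  0.9334  0.0666  5,7
3  QSP  0.0044  0.9956  -
```

Reading the output: each row is one query in input order; the two
probabilities come from the Platt-calibrated SVM and sum to 1; the label is
their argmax. `fired_rules` lists which of the bundled IR-QSP rules the
standardized feature vector satisfies — an independent, human-readable
second opinion (pep1 matches rule 8; pep2's composition is lysine/leucine
rich, typical of the negative class, even though two loose rules fire; pep3
is phenylalanine/tryptophan rich, the QSP signature, without matching any
single rule exactly). Training on the synthetic demo data selected C = 256,
γ = 2⁻⁸ by grid search.

The same steps are available as library calls (`encode_peptides`,
`grid_search_svm`, `train`, `predict_scores`, `run_gasar`, `extract_rules`);
`iqsp select`, `iqsp rules` and `iqsp eval` wrap feature selection, rule
extraction and repeated-round evaluation.

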