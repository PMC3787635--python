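# Methods

## Problem and model

The task is binary classification of proteins as DNA-binding or
nonbinding from sequence-derived evidence alone. Each protein is mapped
to a fixed-length feature vector with up to four blocks — BP, NBP, PP,
EI — and a support vector machine (or one of four comparison
classifiers) is evaluated by repeated stratified k-fold
cross-validation. The package's emphasis is the *feature machinery* and
the *evaluation harness*; it deliberately does not include a residue-level
binding predictor or a PSI-BLAST wrapper — their outputs are input
formats (an annotation TSV dialect and the ASCII PSSM dump).

## Propensity descriptors (BP/NBP)

For a protein of length N with per-residue binding calls and reliability
indices RI ∈ {0,…,10}:

* BP(1) = Σ RI(i) / (10 N) over binding residues. Ranges over [0, 1];
  equals 1 iff every residue is a maximal-confidence binding call.
* BP(2) = Σ_{i=1}^{N−1} 2^(1−i) S_i / (10 (N−1)), where S_i sums the
  mean RI over unordered pairs of binding residues exactly i apart.

NBP(1)/NBP(2) are identical with the nonbinding calls selected. Choices
made where the definitions admit readings:

* **Pair enumeration.** Each unordered pair is counted once, distance =
  |position difference|. An ordered reading would only rescale BP(2) by
  a factor of 2 uniformly, which a downstream standardized classifier
  cannot distinguish.
* **RI = 0.** The index range is taken as 0..10 inclusive; zero-RI calls
  are retained and contribute zero weight rather than being treated as
  missing.
* **Numerics.** Accumulation is in ascending gap order; the weights are
  dyadic so the result is order-stable, and weights underflow to zero
  beyond gap ≈ 1075 with no truncation needed. An O(N²) enumeration
  oracle reproduces BP(2)/NBP(2) to ≤ 1e−12 on exhaustive small tracks
  and randomized tracks (see `tests/test_propensity.py`).
* **Degenerate inputs.** Empty tracks are rejected; BP(2)/NBP(2) require
  N ≥ 2 (the N−1 denominator); tracks with fewer than two selected
  residues score 0 (empty pair sum).

## Physicochemical block (PP)

Amino acid composition (20 percentages) plus
composition/transition/distribution over six properties with
three-group partitions. The group tables are the widely used
three-state partitions from the classical CTD descriptor literature and
ship as a reviewable JSON file; any table of the same shape can be
substituted, and all dimensions are derived from the configuration at
run time. Conventions:

* transitions pool the two orders of a group pair (unordered),
  normalized by N−1;
* distribution uses points (25, 50, 75, 100); the occurrence index for
  point p over c occurrences is max(1, ceil(p·c/100)); groups absent
  from the sequence emit 0 for every point; a 5-point variant adding the
  first occurrence is available via `PPConfig(distribution_points=...)`.

The default dimension is 20 + 6·(3+3+12) = 128. Descriptor
implementations of this family are sometimes quoted with other totals
(e.g. 146 with 5 distribution points); because no single printed total
is recoverable from the textual definition alone, the package treats the
dimension as scheme-determined and never hard-codes it.

## Evolutionary block (EI)

PSSM scores x are normalized by the logistic sigmoid 1/(1+e^(−x)), rows
are pooled by the amino acid at each position, and each pooled block is
summed column-wise, giving 20 × 20 = 400 values. Sums (not means) are
used, so the block scales with residue counts per amino acid; absent
amino acids contribute an all-zero block. Both axes follow the
PSI-BLAST column alphabet (A R N D C Q E G H I L K M F P S T W Y V).
Two exact invariants are enforced by tests: the grand total equals the
sum of the normalized matrix (conservation, ≤ 1e−9), and the vector is
invariant to permuting positions together with their PSSM rows.

## Classification and evaluation

* **Backend.** Default is an SMO-family SVM (libsvm through
  scikit-learn) with linear kernel and C = 1 — the simplest reproducible
  choice, since kernel and cost are free parameters of the method; both
  are exposed. Simple logistic regression, random forest, Gaussian
  naive Bayes and a CART decision tree sit behind the same contract
  (fit + continuous decision score).
* **Standardization.** Features are standardized with training-split
  statistics before fitting (toggleable). Without it the EI block —
  sums over residue counts, so two orders of magnitude larger than the
  propensity block — dominates the margin.
* **Cross-validation.** Repeated stratified k-fold (default 5 folds × 5
  repetitions, fresh partition per repetition, reproducible from one
  seed). Reported metrics are the plain mean of the 25 fold-level
  values; a fold metric with a zero denominator is recorded as absent
  (NaN) and skipped in the mean, never coerced to 0.
* **Metrics.** Accuracy, sensitivity, specificity (percent) and MCC from
  the confusion counts; AUC from continuous decision scores with midrank
  tie handling (equivalently the Mann–Whitney U statistic divided by
  n₊·n₋, asserted in tests). Per-fold AUCs are averaged like the other
  metrics rather than pooling scores across folds; pooled-score ROC
  curves are available for plotting only.

## Dataset preparation

Length filter 50–6000 inclusive on both bounds; alphabet filter
rejecting any letter outside the 20 standard amino acids (X, Z, B, J,
U, O, gaps, stops); greedy redundancy reduction at 40% identity visiting
sequences longest-first so every cluster representative is its longest
member; negative subsampling to the positive count and a stratified
train/test split. The default pairwise identity is a global
edit-distance identity, 1 − d/max(|a|,|b|) via edlib — chosen over a
k-mer heuristic because an exact aligner is available and cheap at
corpus scale — and the `identity_fn` hook accepts any substitute
(e.g. precomputed BLAST/CD-HIT clusters). Every filter returns a report
whose accounting (input = retained + excluded) must balance exactly.

## Synthetic corpora

`gen_proteins` emulates the premise that binding proteins carry many
more predicted binding residues: sequences i.i.d. uniform over the 20
amino acids with lengths uniform on 50–300; per-residue binding-call
probability 0.5 for binding proteins vs 0.05 for nonbinding ones (a
strong enrichment, so the annotation channel separates classes
decisively at the default 200 proteins per class); RI ~ Binomial(10,
0.7) identically in both classes, so RI magnitude itself carries no
label; PSSM scores round(N(0, 2)) clipped to [−10, 13], independent of
class. Consequently the PP and EI channels are signal-free by
construction — passing ablation tests show the *harness* attributes
signal to the right channel, not that any feature block predicts real
DNA-binding. The generator does not model residue composition bias,
binding-site geometry, sequence homology or realistic PSSM structure;
absolute accuracies on real corpora cannot be inferred from it.

`gen_blobs` produces two unit-variance Gaussian classes whose means are
`separation` apart along the first coordinate (separation 6 implies a
Bayes error of ~0.13%), used to sanity-check the CV harness at both the
separable and the label-permuted null ends.

## Problem sizes

The shipped tests and the acceptance script run at the generator's
default conditions: 200 proteins per class (400 total) for the ablation
and rank-sum checks, 400 points for the separable-blob check, 2000 for
the null check, ~1500 tracks for the enumeration oracle and 1000 random
confusion tables for the metric oracle.

## Known limitations

* The annotation TSV requires an RI for nonbinding as well as binding
  calls; residue predictors that score only binding calls need an
  adapter (assign nonbinding calls an RI, e.g. 10 − binding RI).
* The greedy identity clustering is order-dependent (longest-first) and
  quadratic in the number of sequences; for large corpora substitute
  precomputed clusters via `identity_fn`.
* The five classifier backends share one contract but their
  hyperparameters are deliberately left at library defaults except for
  the SVM; the package performs no hyperparameter search.
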