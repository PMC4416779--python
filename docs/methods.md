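# Methods

## Model

The package infers synthetic-lethal (SL) gene pairs from selection signatures
in tumor genomes. The underlying assumption is purifying selection within a
tumor: a clone that loses both members of an SL pair dies, so across a large
cohort the joint loss of an SL pair is depleted relative to what the pair's
single-gene loss rates admit, and inactivation of one member co-occurs with
over-activity of the partner (compensation).

Both signals are measured as conditional per-pair fractions, not as
deviations from an independence expectation: observed co-loss rates of random
gene pairs are *not* the product of single-gene loss rates (losses are
correlated genome-wide), so each fraction conditions on the pair being
"at risk" — at least one member lost, in the event-specific sense — and asks
how often the second hit is present. The five fractions (f1 homozygous
co-loss, f2 heterozygous co-loss, f3 mixed co-loss, f4 co-under-expression,
f5 expression up-down) are defined in the package README and
`pair_features`' module docstring, including the exact numerator and
denominator status sets. Two deliberate subtleties:

* the mixed co-loss denominator pairs a homozygous deletion with a partner in
  {0, −1}; samples at (−2, −2) are outside it, so f1 and f3 condition on
  disjoint event classes;
* a sixth fraction, genomic up-down (duplication/amplification opposite a
  deletion), is computed and reported by the pattern analysis but excluded
  from the classifier's default feature set: empirically it does not separate
  SL pairs from random pairs, only from the (ascertainment-biased) non-SL
  set.

Samples with more than `high_deletion_threshold` (default 2000) homozygously
deleted genes are excluded from f1 only: such hyper-deleted genomes produce
homozygous co-loss for any pair regardless of interaction status. A config
flag can extend the exclusion to f2/f3. Pairs on the same chromosome are
excluded everywhere because arm-level copy-number events co-delete linked
genes.

## Expression status calling

Per tumor sample and gene: z = (x − mean(ref)) / sd(ref) against a reference
panel of normal samples — same-tissue normals when at least
`min_same_tissue_normals` (default 25) exist, otherwise all normals. The
p-value is the two-sided standard-normal tail (the reference panels are
large enough that the normal approximation is standard practice); sd uses
denominator n − 1. P-values are Benjamini–Hochberg adjusted *within each
tumor sample across genes* — matching the per-tumor framing of the calling
procedure — with a `bh_scope: global` switch; status is sign(z) at adjusted
p ≤ 0.05, else 0. A constant reference (sd = 0) yields status 0 with a
logged warning rather than an infinite z.

## Statistics

* SL vs non-SL: one-sided Wilcoxon rank-sum per fraction, exact by
  enumeration when the combined sample is ≤ 20 and tie-free, otherwise the
  normal approximation with tie and continuity corrections
  (`scipy.stats.mannwhitneyu`).
* SL vs random: 1000 draws of 300 random different-chromosome pairs from
  genes having both CNV and expression data; each draw's mean fraction
  (over defined values) is compared with the SL mean in the expected
  direction; p = (n1 + 1)/(n_rand + 1), where n1 counts contradicting draws.
  Ties count as contradictions (conservative), and draws with no defined
  values count as contradictions as well. The expected direction follows the
  observed pattern: random/non-SL pairs have *larger* f1–f4 and *smaller*
  f5 means than SL pairs.
* Bonferroni families: the four co-loss comparisons (f1–f4) share m = 4, the
  two up-down comparisons (f5, genomic up-down) share m = 2, for both test
  types.
* Gene-level controls guard against single-gene confounding: a two-sided
  rank test of per-gene homozygous deletion rates (SL vs non-SL genes) and a
  one-sided test of over-expression rates (non-SL vs random genes).

## Classifier

Training sets are heavily imbalanced (≈ 4.6% positives at realistic label
counts), so each of R under-sample replicates (default 10; 100 mirrors the
original protocol at ~10x the cost) draws a balanced set keeping all
positives. Seven base learners are fitted per replicate; the prediction is
the arithmetic mean of every learner's SL probability across replicates —
averaging over replicates lets all negatives contribute while keeping each
fit balanced. The seven default scikit-learn learners cover the intended
families: AdaBoost, a pruned decision tree (C4.5-like), gradient (logit)
boosting, a random forest, logistic regression, and — because no maintained
Python RIPPER/PART rule inducers exist — a depth-3 decision tree (a compact
rule list) and extra-trees as the two rule-style stand-ins. All are
replaceable via `EnsembleConfig.base_learners`; the method's claim rests on
ensemble averaging of weak probabilistic learners, not on any one
implementation.

Evaluation is repeated stratified 10-fold cross-validation (stratified
because at 4.6% prevalence unstratified folds can lack positives).
Under-sampling and NaN-median imputation are recomputed inside each training
fold, so no test information leaks. The mean AUC is the mean of per-repeat
pooled out-of-fold AUCs; the mean ROC curve is vertically averaged on a
101-point FPR grid, the PR curve on a recall grid, with standard errors
across repeats. Genome-wide prediction enumerates different-chromosome pairs
in streamed blocks, scores them, and keeps pairs at or above the probability
threshold (default 0.81, the operating point historically associated with
~67% precision at ~10% recall on real labels).

## Synthetic cohorts

`synthetic_data.generate_cohort` draws every background gene i.i.d. per
sample from categorical status distributions. Each planted SL pair replaces
the two genes' columns with draws from the reweighted product distribution:
co-loss cells (both members in {−1, −2}; both −1 for expression) multiplied
by ρ ∈ [0, 1], up-down cells (one member in {1, 2} against one in {−1, −2};
(−1, 1)-type cells for expression) multiplied by κ ≥ 1, then renormalized.
Reweighting (rather than rejection sampling) gives the exact target joint in
O(1) per draw; ρ = κ = 1 recovers an exchangeable null. Hyper-deleted
samples are appended with an elevated homozygous-deletion rate (default 0.2
across all genes) to exercise the f1 filter.

Default background rates are a deliberate desk-scale choice. Real
pan-cancer panels show per-gene homozygous-deletion rates near 0.004 — over
~14,000 samples. At the default 500-sample cohort that rate yields
essentially zero homozygous co-loss events, leaving f1 untestable; the
defaults therefore scale the loss and over/under-expression rates up
(hom-del 0.03, het-del 0.12, dup 0.04, amp 0.02, under/over-expression 0.08)
so per-gene event counts at 500 samples sit in the same informative regime
as the real panel. Panel-scale rates ship as `TCGA_SCALE_CNV_PROBS` /
`TCGA_SCALE_EXPR_PROBS` for users simulating at full cohort size. The
generator emulates marginal rates, planted pair effects, chromosome
assignment and hyper-deleted samples; it does **not** model arm-level
segment correlation between neighboring genes, tumor-type heterogeneity, or
gene-length effects — so a green simulation test establishes that the
pipeline recovers planted pair-level effects, not that real-data effect
sizes will match.

`generate_expression_with_normals` provides Gaussian per-gene expression with
configurable tumor-cell shifts (in units of the reference sd) to exercise the
status caller, including the ≥ 25 same-tissue-normals rule.

## Numerical choices and degenerate inputs

* Fractions with empty denominators are NaN; pattern statistics use defined
  values only; the classifier imputes NaNs with training-set medians
  (training fold only).
* Pairs are unordered; the canonical form sorts the two gene ids
  lexicographically, so all fractions are symmetric in A and B by
  construction (property-tested).
* Chromosome labels are compared as strings after stripping an optional
  "chr" prefix; pairs with unannotated genes are dropped with a log entry.
* Prediction output orders rows by descending probability with a
  lexicographic tie-break, probabilities at 6 decimals.
* All stochastic stages take explicit seeds; a master seed derives
  per-component seeds via `numpy.random.default_rng`, and equal seeds give
  bit-identical cohorts, fold splits and randomization draws.

## Limitations

* The published headline numbers (AUC 0.75 on 270/5660 TCGA-derived labeled
  pairs; 591,000 predictions at threshold 0.81) require the TCGA CNV/RNAseq
  downloads and the supplementary labeled-pair list, which cannot ship here;
  the package reproduces the *method* and validates it on planted synthetic
  cohorts.
* Probabilities are not calibrated; the 0.81 threshold is an operating point
  inherited from cross-validated precision, not a posterior probability.
* No tumor-type stratification: fractions pool all samples.
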