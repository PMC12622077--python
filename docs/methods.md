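# Methods

`bloodaudit` implements an analysis chain for case/control whole-blood
transcriptomics in which the first-class question is not "which genes are
differentially expressed?" but "how much of the classification signal in this
dataset is systematic bias?". This note documents the models, the synthetic
cohorts everything is tested on, the numerical choices, and the limits of what
the tests demonstrate.

## The bias audit

A dataset with no exploitable artefacts should give near-chance classification
from *randomly chosen* feature sets. The audit draws `n_iterations` gene sets
of `set_size` features (defaults 10,000 and 75) uniformly without replacement,
and for each set trains an L2-penalized logistic regression (unit inverse
regularization strength `C = 1`, features z-scored inside each training fold)
under leave-one-out cross-validation. Each iteration yields a single AUC,
computed once from the pooled out-of-fold scores by the rank (Mann–Whitney)
formula with midranks. LOOCV produces exactly one score per sample, so pooling
is the only coherent way to form an AUC; fold-averaging is undefined.

The mean of the AUC distribution is the bias measure. Comparisons between
dataset variants (raw vs. batch-adjusted vs. composition-adjusted) replay the
*same* gene-set manifest on each variant and use a paired two-sided Wilcoxon
signed-rank test on the per-iteration AUCs; if every paired difference is zero
the p-value is reported as 1.0 by convention. Fresh-manifest comparisons fall
back to a two-sided rank-sum test.

The logistic solver is an in-house Newton iteration on the penalized likelihood
(intercept unpenalized), warm-started per fold from the full-data fit. It
minimizes the same objective as the standard library estimator — a unit test
holds it to the library refit to 1e-9 on the resulting AUC — and exists purely
because the audit refits the model `n_iterations × n_samples` times.

## Synthetic cohorts

The generator produces the statistical structure the chain assumes, not
biological realism:

- **Mixtures.** Linear-scale expression is `S f_i`, a signature matrix (genes ×
  cell types, disjoint marker blocks at ≥ 8-fold enrichment) times per-sample
  Dirichlet cell fractions, then `log2(x + 1)`. Mixing on the linear scale
  matches the physical interpretation of whole blood. Default concentrations
  `(11, 5, 1.5, 2, 0.5)` give mean fractions ≈ (0.55, 0.25, 0.075, 0.10,
  0.025) — neutrophils dominating, as in adult blood.
- **Composition shift.** Cases' neutrophil concentration parameter is moved so
  the mean fraction rises by `neutrophil_shift` (default 0.05, the magnitude
  reported for AD blood); perturbing the concentration rather than the drawn
  fractions keeps the simplex constraint exact.
- **Batch structure.** 18 plates nested in 3 sites. Each plate has a location
  effect with two parts: a *shared* per-plate offset (a "plate total signal"
  shift common to all genes) and an independent per-gene component, both
  N(0, `plate_location_sd`); scale effects are log-normal multipliers on the
  technical noise. When `plate_diagnosis_assoc > 0`, cases are preferentially
  assigned to plates with a positive shared offset (probability tilt `1 ±
  assoc`), so the batch layout itself predicts diagnosis — the artefact the
  audit exists to detect.
- **Disease effects.** `n_de_genes` genes get a ±`de_effect_log2` multiplier
  on the linear mixture in cases; a `sex_specific_fraction` of them are active
  in one sex only (effect-present-in-one-sex, not sign-flipped), mirroring
  pathway findings reported only in one sex.
- **Replicates.** Technical replicates share the subject's fractions,
  biological noise, plate and site, and redraw only technical noise;
  `technical_sd < biological_sd` by default (0.2 vs 0.6), so within-replicate
  correlation must exceed between-subject correlation.
- **MRI block.** A latent severity `t_i = shift·case_i + N(0,1)` drives 136
  features `loading_j · t_i + N(0,1)`. The default shift 1.812 puts the
  Bayes-optimal AUC on the latent at Φ(shift/√2) ≈ 0.90.
- **Ages** are normal, truncated to [50, 95], with a 4-year case excess by
  default so propensity matching has something to correct.

One `numpy` Generator seeded from the config drives everything; identical
configs give bit-identical cohorts.

**The standard confounded cohort** (`SyntheticCohortConfig.confounded_audit`)
is the benchmark for the adjustment chain: 500 subjects, 2000 genes, no planted
disease genes (so audit AUC is pure bias), plate–diagnosis association 0.3,
neutrophil shift 0.05, plate effect scale 0.5. Two sizing choices matter and
were fixed before freezing the test conditions. First, plate effects need a
shared total-signal component: purely per-gene random plate offsets are almost
unlearnable by a linear classifier from 75 random genes and act mostly as
noise. Second, supervised (diagnosis-preserving) batch correction removes
batch-mean noise while the label-aligned noise component is protected, which
*raises* the audit mean by a few hundredths on small cohorts; at 500 subjects
(~28 per plate) the genuine plate bias dominates and the published ordering —
raw > plate/site-adjusted > neutrophil-adjusted — is strict.

What passing does not show: the generator has Gaussian noise, exact linear
mixing, and batch effects independent of expression level. Real arrays have
intensity-dependent noise, probe-level saturation, and correlated gene
modules; audit magnitudes here do not transfer, only the qualitative behaviour
of the chain.

## Probe-set rebuilding

From a probe/genome alignment table: keep probes with exactly one genomic
match; drop probes that have **both** a mean linear intensity below the
`signal_quantile` (default 0.1) quantile of probe means **and** a coefficient
of variation below `cv_threshold` (default 0.05) — the conjunction is the
load-bearing rule, the thresholds are exposed; group survivors by transcript,
requiring at least 3 probes per probe-set; summarize a probe-set as the median
of member probes' log2 intensities (robust and probe-order invariant;
median-polish would be the natural alternative). Normalization is a documented
median-scaling stand-in: each sample column is shifted so its median equals
the global median of column medians. A row-wise SD filter (log2 scale)
restricts to expressed features.

## Deconvolution

Cell fractions are estimated per sample by non-negative least squares,
`min ‖S w − m‖₂, w ≥ 0`, on the linear scale (`2^x − 1`, with a flag for
`2^x` inputs), restricted to signature genes. Fractions are `w / Σw`; `Σw` is
kept as the absolute immune signal. The adjustment covariate is the z-scored
(population sd, divisor n) neutrophil fraction. NNLS is the minimal faithful
linear-mixture solver; support-vector refinements change estimates by less
than the noise floor at these design sizes.

## Batch and covariate adjustment

Categorical batches use the canonical parametric empirical-Bayes
location/scale model: standardize per gene retaining the preserved design
(diagnosis), estimate per-batch locations `γ̂` and scales `δ̂²`, shrink with a
normal / inverse-gamma prior whose hyperparameters come from across-gene
moments, solve the posterior by fixed-point iteration, correct, and re-inject
the preserved effects. A fixture comparison against the R reference
implementation reproduces its output decile-for-decile. Steps are applied
sequentially (plate, then site), matching the stepwise protocol. A single
batch level is the identity.

Two calibration facts are easy to misread and are encoded in the tests:

- In-sample, batch ANOVA p-values after adjustment are **conservative**
  (concentrated near 1), because estimated batch means absorb batch-mean noise
  along with the true effects. This is intrinsic — the R reference behaves
  identically — so the in-sample check is "no residual batch signal", not
  uniformity.
- Uniform calibration holds **out-of-sample**: a model fitted on a large
  independent set and applied to held-out samples of the same batches leaves
  fresh batch-mean noise intact. `apply_adjustment` accepts new-sample batch
  labels for exactly this use.

The continuous (neutrophil) step is per-gene OLS on `1 + diagnosis +
covariate`, subtracting only the fitted covariate term, so the diagnosis
effect is retained. For a gene whose class difference is purely
composition-driven, the covariate term absorbs it and the audit signal drops —
which is the point of the step.

## Matching

Propensity scores come from a maximum-likelihood logistic fit of diagnosis on
sex (0/1) and age (years), standardized internally and reported on the
original scale; quasi-separation is flagged. Matching is greedy 1:1 nearest
neighbour on the logit without replacement: the minority class drives,
processed in descending logit order, ties broken lexically by sample id; an
optional caliper (logit distance) discards poor pairs. Balance is reported as
the standardized mean difference `(m₁ − m₀)/√((s₁² + s₀²)/2)` before and after
matching. With near-equal arms, 1:1 matching without a caliper keeps everyone
and cannot improve balance; the balance benchmark therefore uses an imbalanced
cohort and a 0.1·sd(logit) caliper.

## Feature selection

mRMR is the FCQ variant: relevance is the one-way ANOVA F statistic against
the binary label, redundancy the mean absolute Pearson correlation with the
already-selected set (floored at 1e-6), combined as a quotient (difference
scheme behind a flag). Greedy, deterministic, lexical tie-breaks. The ensemble
runs 50 repeats on stratified (diagnosis × sex) 80% subsamples; a feature at
position p of a length-L list scores L+1−p, absent features score 0, and the
consensus is the mean score. The scan evaluates nested head subsets (50, 60,
…, 500) on a held-out set disjoint by subject id and picks the best subset
with ≤ 200 features, ties to the fewest.

## Modeling

Model families: logistic regression, SVM, random forest, each a pipeline with
training-fold standardization. Default grids: C ∈ {0.01, 0.1, 1, 10};
kernel {linear, rbf} × C {0.1, 1, 10}; trees {200, 500} × depth {∞, 8}. Inner
tuning is an exhaustive grid search with nested stratified CV on training data
only. Evaluation is either matched-train/held-out-test or repeated stratified
k-fold (50 × 5 by default, stratified on diagnosis × sex), reporting AUC,
sensitivity and specificity at the 0.5-probability (or 0 decision-value)
threshold, and accuracy within each sex, averaged unweighted over folds, with
the per-fold AUC vector kept for paired Wilcoxon model comparisons. Fusion is
column concatenation of blocks with block-prefixed names; scaling lives in the
model pipeline so no test-fold statistics leak. Attribution is a sampled-
permutation Shapley estimate against the training-mean baseline; on additive
models it reduces exactly to `w_j (x_j − mean_j)`, which the tests use as a
closed-form oracle. The fusion acceptance check runs at 10 × 5 folds with the
singleton logistic grid — the qualitative dominance property is stable at that
size.

## Differential expression

The SAM statistic is `d_g = (mean₁ − mean₀)/(s_g + s₀)` with the pooled-
variance standard error; `s₀ = median(s_g)` by default ("auto"), a simpler and
deterministic alternative to the MAD-minimizing grid. FDR comes from label
permutations (exhaustive enumeration when the distinct permutation count is
below the request, flagged in the result): for each observed |d| threshold,
FDR = median permuted exceedance count / observed count; a gene's q is the
step-up minimum over thresholds at which it is called, giving q monotone
non-increasing in |d|.

RRHO compares two signed rankings over one universe on a step grid (default
⌈N/100⌉): each cell holds the exact hypergeometric over-enrichment tail
probability of the head-overlap, with a signed display relative to the
expected overlap. The map is exact (no normal approximation) and transposes
under list exchange. Grid p-values are reported uncorrected, noted in the
output metadata. The enrichment zone is the intersection at the most
significant concordant cell, head-head vs tail-tail, ties toward the smaller
corner; note that for two identical rankings the most significant cell is the
mid-list diagonal cell, so the zone is the top half, not the first grid block.

ORA is the exact hypergeometric tail against the expressed-gene background
(sets intersected with the background first; the query must be contained in
it), Benjamini–Hochberg corrected across the collection.

## Problem sizes used by the test suite

Unit tests run on cohorts of 100–400 subjects and 20–2000 genes. The
end-to-end checks use: null audit at n = 300, 2000 genes, 200 iterations;
bias-ordering on the standard confounded cohort (n = 500) with 200 shared
gene sets; deconvolution at 100 samples / 200 genes / 10% noise; batch
recovery at n = 400 / 500 genes; SAM calibration over 50 null simulations;
fusion at 346 subjects / 400 genes / 136 MRI features with 10 × 5 folds.

## Known limitations

- The generator's batch model is additive on log2 expression; intensity-
  dependent batch effects are not emulated.
- Deconvolution assumes the true signature is known; reference mismatch, the
  dominant error source on real data, is out of scope.
- The audit's absolute AUC levels depend on every generator scale; only
  orderings and calibration points are asserted.
- Supervised batch correction's small label-leakage inflation (see above)
  means audit comparisons should always be made on variants adjusted with the
  same preserved design, never raw-vs-adjusted across different designs.
- RRHO permutation-corrected p-values and SAM's delta-grid threshold policy
  are not implemented.
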