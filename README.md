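# bloodaudit

Bias auditing and matched multimodal classification for case/control blood
transcriptomics.

Whole-blood expression cohorts — e.g. Alzheimer's disease (AD) vs. control
microarray studies — routinely carry systematic structure that has nothing to
do with disease: plate and site batch effects, and shifts in white-blood-cell
composition (neutrophils alone are ~40–60% of leukocytes, and a few percent
difference in neutrophil fraction between groups moves thousands of genes).
Classifiers trained on such data report inflated performance that does not
replicate. `bloodaudit` implements the full analysis chain for detecting,
quantifying and removing this bias, plus the downstream matched
classification protocol:

- **synthetic** — cohort generator: linear-scale cell-type mixtures with a
  group-shifted neutrophil fraction, 18-plate/3-site batch structure with an
  optional plate–diagnosis association, planted (optionally sex-specific)
  log2 disease effects, technical replicates, and an MRI-like feature block
  driven by a latent severity variable.
- **probesets** — probe filtering (unique genomic match; drop low-signal AND
  low-CV probes), transcript-level probe-sets (≥ 3 probes), median
  summarization, median-scale normalization, SD expression filter.
- **deconvolution** — non-negative least squares cell-fraction estimation
  against a signature matrix; scaled neutrophil covariate; PC–covariate
  association diagnostics.
- **batch** — parametric empirical-Bayes (ComBat-style) location/scale batch
  correction preserving the diagnosis effect, applied stepwise (plate, then
  site), and per-gene OLS residualization on the neutrophil estimate.
- **audit** — the sampling-at-random bias audit: AUC distribution of
  leave-one-out cross-validated logistic regression on random 75-gene sets,
  with paired Wilcoxon comparisons between adjustment variants and
  technical-replicate concordance diagnostics.
- **matching** — propensity-score (sex, age) greedy nearest-neighbour 1:1
  matching with SMD balance diagnostics.
- **selection** — two-step ensemble mRMR: 50 stratified 80% subsamples, rank
  aggregation (top = L … absent = 0), feature-count scan, best subset ≤ 200.
- **modeling** — logistic / SVM / random-forest pipelines, holdout and
  repeated stratified 5-fold CV (diagnosis × sex), concatenation fusion of
  transcriptomics and MRI blocks, sex-stratified metrics, paired fold tests,
  permutation-sampling Shapley importance.
- **dge** — SAM-style moderated statistic with permutation FDR, rank-rank
  hypergeometric overlap (RRHO) maps between sex-stratified contrasts, and
  hypergeometric over-representation against the expressed background.

The statistic at the audit's core: for gene-set iteration *k*,
AUC_k = P(score(case) > score(control)) estimated by the Mann–Whitney rank
formula on pooled leave-one-out scores of an L2 logistic model trained on 75
random features. E[AUC] ≈ 0.5 on unbiased data; the excess over 0.5 measures
dataset-level bias, and the drop in mean AUC after ComBat plate/site
adjustment and neutrophil residualization measures how much of the bias each
step explains.

## Worked example

Audit a confounded synthetic cohort (500 subjects, 2000 genes, plate–diagnosis
association 0.3, +0.05 neutrophil shift in cases, no disease genes), then
remove batch and composition signal and re-audit with the same gene sets:

```python
import numpy as np
from bloodaudit import synthetic as syn, audit, batch, deconvolution as dec

cfg = syn.SyntheticCohortConfig.confounded_audit(seed=1)
cohort = syn.generate_cohort(cfg)
y = (cohort.metadata["diagnosis"] == "case").to_numpy().astype(int)

raw = cohort.expression
adjusted = batch.adjust_stepwise(raw, cohort.metadata,
                                 steps=["plate", "site"], preserve="diagnosis")
est = dec.estimate_fractions(adjusted, cohort.signature)
neut = batch.residualize_continuous(
    adjusted, dec.scale_covariate(est, "neutrophil"),
    preserve=cohort.metadata["diagnosis"])

sets = audit.sample_gene_sets(list(raw.index), set_size=75, n_iterations=50, seed=2)
results = {}
for name, mat in [("raw", raw), ("plate/site-adjusted", adjusted),
                  ("neutrophil-adjusted", neut)]:
    res = audit.run_audit(mat, y, audit.AuditConfig(
        n_iterations=50, set_size=75, seed=2, shared_set_manifest=sets))
    results[name] = res
    print(f"{name:>22}: {res.summary()}")

cmp1 = audit.compare_audits(results["raw"], results["plate/site-adjusted"])
cmp2 = audit.compare_audits(results["plate/site-adjusted"], results["neutrophil-adjusted"])
print(f"raw vs adjusted:        paired Wilcoxon p = {cmp1.pvalue:.2g}")
print(f"adjusted vs neutrophil: paired Wilcoxon p = {cmp2.pvalue:.2g}")
```

Output:

```
                   raw: 0.626±0.02 AUC over 50 iterations
   plate/site-adjusted: 0.571±0.03 AUC over 50 iterations
   neutrophil-adjusted: 0.554±0.03 AUC over 50 iterations
raw vs adjusted:        paired Wilcoxon p = 1.8e-15
adjusted vs neutrophil: paired Wilcoxon p = 3.9e-10
```

Read: random gene sets classify diagnosis at AUC 0.63 on the raw matrix even
though *no* gene carries a disease effect — the signal is plate layout and
neutrophil composition. Plate/site correction removes about half the excess;
residualizing the deconvolution-estimated neutrophil fraction removes most of
the rest. The remaining excess over 0.5 is the composition difference that is
collinear with diagnosis and deliberately preserved by the supervised
adjustment.

A command-line interface mirrors the library
(`pipeline simulate | probesets | deconvolve | adjust | audit | match |
select | train | cv | importance | dge | rrho | ora`); run
`pipeline --help` for the subcommand contracts.

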