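# Methods

`epigx` re-implements, as a tested and reusable pipeline, an integrated
genetic–epigenetic analysis of one target CpG against a quantitative
glycemic exposure (HbA1c, %). This note documents the models, the synthetic
cohort generator, the numerical conventions, and the open design choices.

## The analysis model

All association machinery is ordinary least squares with classical
(homoskedastic) t-based p-values. The five scan families, per feature:

| scan        | model                                                   | focal term |
|-------------|---------------------------------------------------------|------------|
| EWAS        | HbA1c ~ β_i + age + sex + BMI                            | β_i        |
| polymorphic | same model, restricted to polymorphic-flagged probes     | β_i        |
| meQTL       | β_T ~ SNP_i + age                                        | SNP_i      |
| GxE         | β_T ~ SNP_i×HbA1c + SNP_i + HbA1c + age                  | interaction|
| GxMeth      | HbA1c ~ β_T×SNP_i + SNP_i + β_T + age + sex + BMI        | interaction|

where β_T is the target probe's beta value. Adjusted R² is
1 − (1−R²)(n−1)/(n−p−1). Every fit uses complete-case deletion and records
`n_used`. EWAS and polymorphic scans carry Benjamini–Hochberg q-values
(each family adjusted independently); the GxMeth scan carries Bonferroni
adjustment at family size = SNPs tested, for the interaction and the
additive SNP term separately. Scan output is sorted by focal p, ties broken
by feature id, so output order is deterministic.

SNP–probe proximity: cis = same chromosome and distance ≤ 1 Mb (inclusive
boundary), long-range cis = same chromosome beyond 1 Mb, trans = different
chromosome. Positions are 1-based; distance is |snp_pos − probe_pos|.

## Genotype QC and phenotype rules

* MAF filter: empirical MAF from non-missing dosages, folded to ≤ 0.5;
  SNPs at MAF ≤ 0.05 (configurable) are dropped.
* LD pruning: sliding windows of 50 SNPs advancing by 5, removing one SNP
  of any retained pair with dosage r² > 0.5. The later SNP in position
  order is dropped — a deterministic convention; removal is permanent, so
  pruning is idempotent and the output is always a column subset.
* Glycemic classes partition (0, ∞): control = (0, 5.7], prediabetic =
  (5.7, 6.5), diabetic = [6.5, ∞). The clinical cut points are quoted with
  "≤ 5.7" and "≥ 6.5", which leaves the boundary values themselves
  ambiguous between adjacent bins; assigning them to the closed ends
  honours both inequalities literally. This is a convention, not a
  clinical claim.
* Exclusions: control-class subjects self-reporting a diabetes diagnosis,
  and non-diabetic-class subjects self-reporting anti-diabetic medication,
  are flagged (never deleted — phenotype values are untouched).

## Stochastic epimutations (SEMs)

A SEM is a beta value outside Tukey-style fences at 3×IQR: HMO above
Q3 + 3×IQR, LMO below Q1 − 3×IQR. Conventions:

* quartiles by linear interpolation between order statistics (the numpy
  default) — the 3×IQR rule is usually cited without a quantile
  convention, so we fix the common one;
* fences computed from **all** values of the probe, including candidate
  outliers (the simple published definition, not leave-one-out);
* strict comparison: a value equal to a fence is not an outlier;
* probes with fewer than 8 non-missing values are skipped with a warning.

Enrichment is tested at the subject level (subjects with ≥ 1 SEM vs
without, diabetic vs non-diabetic) because subjects, not calls, are the
independent units. The two-tailed p comes from the Fisher exact
(hypergeometric) test; the odds ratio is the conditional MLE with an exact
conditional 95% CI obtained by inverting the noncentral hypergeometric
tails — consistent with the exact test. Degenerate tables (a zero margin)
report an undefined OR rather than failing.

## Step-wise model construction

Candidates (SNP main effects, the exposure, SNP×exposure interactions) are
ranked by univariate adjusted R² (descending, ties by name) after an entry
screen (defaults mirror the analysis constants: adj R² ≥ 0.03 for meQTL
candidates, ≥ 0.1550 for GxE terms). Each candidate is added in rank
order and retained only if (a) its coefficient p < 0.05 in the joint fit
and (b) the nested extra-sum-of-squares F-test p < 0.05. After each
accepted addition, previously retained candidates that lost significance
are dropped in one sweep — the dropping schedule is not prescribed
anywhere, so a single post-acceptance sweep was chosen for determinism.
Interaction candidates bring their missing parents with them; the
hierarchy (interaction ⇒ both parents present) is never violated, and
base covariates are never dropped. Candidates whose addition makes the
design condition number exceed 1e10 are skipped and logged.

Stratified genotype comparisons use Welch's t between genotype groups with
≥ 3 subjects, Holm-adjusted within each stratum's family of pairwise
tests; Δβ is reported in percentage points. The effect size is a
pooled-SD standardized mean difference with a seeded bootstrap percentile
95% CI (2,000 resamples by default). The estimator behind effect sizes in
comparable published analyses is typically unnamed; we make ours explicit
and do not attempt to match any externally printed value.

## Classification

The balanced random forest (BRF) is built directly on sklearn decision
trees: each of the 500 trees (default) trains on a balanced bootstrap —
`n_minority` subjects drawn with replacement from each class — so every
tree sees equal class counts (recorded per tree as an instrumentation
hook). Defaults: √p features per split, unlimited depth, minimum leaf 1;
all configurable. Forest probabilities are the mean of per-tree
probabilities; Gini importance is the mean of per-tree impurity
importances.

Evaluation: repeated stratified k-fold CV (10 splits × 3 repeats by
default), the more severe dysglycemic class positive. AUC uses the
Mann–Whitney rank formulation with midrank tie correction;
sensitivity/specificity/precision at a fixed 0.5 threshold. Aggregate
metrics are per-fold means (pooled-prediction aggregation available via
`aggregate="pooled"`); the confusion matrix is pooled across folds.

Feature selection mirrors the forest-centric design: an implicit screen
keeps features with importance above the mean importance (plus always-keep
covariates and the target CpG), then Gini pruning keeps the top-k
(default 13) by CV-averaged importance, ties broken lexicographically,
and refits. Selecting on the full dataset before CV risks selection
leakage; both the screen-then-CV ordering and a fully nested ordering can
be composed from the public functions, and the acceptance checks use
fixed feature sets so no selection leakage can inflate them.

The three-class task is handled as binary contrasts (control vs diabetic
is the primary one); no multinomial model is fitted.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **Genotypes**: per-SNP MAF uniform on a configured range (default
  0.05–0.5), dosages Binomial(2, MAF) — Hardy–Weinberg, no LD (a
  deliberate simplification; LD pruning is exercised with duplicated /
  perturbed columns in tests). Optional uniform missingness.
* **Exposure**: HbA1c from a three-component truncated-normal mixture —
  components (mean, sd) = (5.34, 0.26), (5.96, 0.21), (8.02, 1.84)
  truncated to the control/prediabetic/diabetic bins, mixed at the
  configured class proportions (default 142:274:90). These defaults are
  plausible cohort values, not fitting targets.
* **Covariates**: age normal with stratum means 45.3/46.7/52.1 (sd 8),
  BMI log-normal with stratum medians 31/33/37, sex Bernoulli(0.75
  female) — the diabetic stratum is older and heavier, as in real cohorts,
  which is what gives a covariate-only classifier its signal.
* **Target probe**: latent logit-scale value = logit(0.66) + 0.35 × (sum
  of scaled standardized terms + scaled noise), mapped through the
  logistic so betas stay in (0, 1). Terms: exposure (default latent
  variance fraction 0.15, negative sign — demethylation with rising
  HbA1c), age (0.01), planted SNP main effects and SNP×exposure
  interactions at configured fractions. Terms are sequentially
  orthogonalized and the noise residualized against them, so each planted
  term explains **exactly** its configured variance fraction of the latent
  variance in the emitted sample; on the beta scale the logistic map
  attenuates this only slightly at these magnitudes.
* **Null probes**: independent logit-normal noise (baseline U(0.2, 0.8),
  logit sd 0.3). Probes carrying planted SEMs use a mid-range baseline
  (U(0.40, 0.55)) and tighter noise (logit sd 0.1) so the 3×IQR fences
  leave headroom inside [0, 1]; outliers are placed halfway between the
  fence and the boundary and verified against fences recomputed on the
  full vector.
* **CpG×SNP (GxMeth) effects**: added to HbA1c after the methylation is
  generated, as effect × standardized(β_T×SNP product), with the effect on
  the HbA1c % scale. Glycemic classes are binned from the final HbA1c, so
  realized class proportions drift slightly from the configured mixture
  when GxMeth effects are planted.

All randomness flows from the single `SimConfig.seed` through numpy
seed-sequence spawning; identical configs give byte-identical cohorts.

What the generator does **not** emulate: LD structure, cell-type
composition, batch/array effects, probe cross-reactivity, genotype–
covariate confounding (unless planted). Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
model, not robustness to real-data artifacts.

## Problem sizes and tolerances

Monte-Carlo checks use the sizes at which the relevant properties are
stable: n = 500 subjects for scan calibration and power (100 seeds for
error-rate and power checks; 1,000 probes / 2,000 SNPs per null seed),
50 paired seeds for the classifier comparison (100 trees, 5×2-fold CV),
and 40–60 seeds for the script-level summaries. Scan-vs-reference
equivalence is asserted to 1e-8; exact arithmetic (quantiles, Fisher
enumeration, bookkeeping) to machine precision or printed precision.

## Known limitations

* No mixed models, kinship or ancestry adjustment; p-values assume
  homoskedastic independent errors.
* The LD pruner is O(window²) per window — fine at simulated scale, not
  tuned for millions of SNPs.
* The G+E two-SNP fit is exposed as a utility (`fit_ge_pair`), not a
  genome-wide pair scan: no pairing rule for (SNP_i, SNP_j) is defined in
  the source analysis.
* Cohort-specific coefficient tables from the motivating study are not
  reproducible without its (undeposited) data; the package validates
  against synthetic ground truth and printed bookkeeping instead.
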