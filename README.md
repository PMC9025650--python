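# epigx

Integrated genetic–epigenetic analysis of a single target CpG against a
quantitative exposure, packaged as a tested, reusable pipeline.

The scientific setting: methylation at one focal CpG (a beta value
β_T ∈ [0, 1], e.g. a probe in a 3′UTR) tracks a clinical exposure such as
glycated hemoglobin (HbA1c, %), but that association is confounded by
genetic variation acting on the CpG both independently of the exposure and
in interaction with it. `epigx` implements the full analysis around such a
probe for epigenomics researchers:

* **EWAS**: per-probe OLS of the exposure on methylation, adjusted for
  age, sex and BMI (`HbA1c ~ β_i + age + sex + BMI`), with
  Benjamini–Hochberg FDR control; a variant restricted to probes with
  polymorphisms at the target site.
* **Stochastic epimutation (SEM) filtering**: outliers beyond Tukey-style
  3×IQR fences — high methylation outliers above Q3 + 3×IQR, low below
  Q1 − 3×IQR — with burden summaries, exact Fisher case–control
  enrichment, and probe filtering.
* **meQTL / GxE / GxMeth scans** anchored on the target CpG:
  `β_T ~ SNP_i + age` (partitioned into cis ≤ 1 Mb, long-range cis,
  trans), `β_T ~ SNP_i×HbA1c + SNP_i + HbA1c + age` (interaction p ranks
  SNPs), and `HbA1c ~ β_T×SNP_i + SNP_i + β_T + age + sex + BMI` with
  Bonferroni control.
* **Step-wise integrated variance models**: candidates ranked by
  univariate adjusted R², retained only while significant and while the
  nested-model F-test shows a significant gain; genotype-stratified
  methylation comparisons with Holm correction.
* **Classification**: logistic baselines and a balanced random forest
  (each tree trained on an equal-size under-sampled bootstrap of both
  classes) under repeated stratified cross-validation, with implicit
  forest-based feature selection and Gini-importance pruning.
* **Synthetic cohorts** (`epigx.synthdata`): genotypes at Hardy–Weinberg
  proportions, a right-skewed three-stratum exposure, logit-normal
  methylation with planted meQTL / interaction effects of exact latent
  variance fractions, planted SEM outliers, and an imbalanced glycemic
  class — with ground truth for every downstream stage.

Genotype QC (MAF > 5% filter, windowed 50/5/0.5 LD pruning on additive
dosages), HbA1c binning at the clinical 5.7/6.5 cut points, and
self-report-based exclusion rules are included. See `docs/methods.md` for
models, conventions and limitations.

## Worked example

```python
from epigx.synthdata import SimConfig, simulate_cohort
from epigx import dataio, scans, semfilter

cfg = SimConfig(n_subjects=500, n_probes=200, n_snps=1000, seed=7,
                planted_meqtl=[("snp_00010", 0.05)],
                planted_gxe=[("snp_00020", 0.05)],
                planted_gxmeth=[("snp_00030", 0.9)],
                planted_sem=[("cg_00007", 3, "high")])
samples, meth, geno, truth = simulate_cohort(cfg)
samples = dataio.apply_exclusions(samples)

calls = semfilter.detect_sems(meth)           # 3×IQR fence outliers
meth = semfilter.filter_sem_probes(meth, calls,
                                   target_probe=cfg.target_probe_id)

ewas = scans.ewas_scan(meth, samples)
print(ewas[["feature_id", "coef_meth", "focal_p", "q_value"]].head(3))

target = meth.values[cfg.target_probe_id]
gxm = scans.gxmeth_scan(target, geno, samples)
print(gxm[["feature_id", "coef_meth:snp", "focal_p", "bonferroni_p"]].head(3))
```

Output:

```
feature_id  coef_meth      focal_p      q_value
 cg_target  -8.209881 2.851341e-19 5.503088e-17
  cg_00047   3.395893 1.047449e-03 9.945521e-02
  cg_00019  -3.162386 1.545936e-03 9.945521e-02
feature_id  coef_meth:snp      focal_p  bonferroni_p
 snp_00030      20.452126 8.702260e-57  8.702260e-54
 snp_00468      -6.337524 1.142950e-07  1.142950e-04
 snp_00170      -6.551042 4.091379e-06  4.091379e-03
```

The planted target probe tops the EWAS (negative coefficient: higher
methylation, lower HbA1c — i.e. demethylation with hyperglycemia) and is
the only probe surviving FDR at 5%; the planted CpG×SNP interaction SNP
tops the GxMeth scan and survives Bonferroni at family size 1,000, while
the runners-up are null SNPs at the expected chance level. Of the 10 SEM
calls, the 3 planted high-methylation outliers on `cg_00007` are all
recovered (the rest are chance calls on null probes; the target probe is
never dropped).

A CLI wraps the pipeline end to end (YAML-configurable thresholds, TSV/JSON
artifacts, deterministic under a fixed seed):

```sh
epigx run-all --config cfg.yaml --out results/ --seed 1
# or per stage: epigx simulate|qc|sem|scan|model|classify ...
```

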