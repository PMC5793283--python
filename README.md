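# vitdmr

One-sample Mendelian randomization of vitamin D status against cancer
incidence and mortality, built around an unweighted 5-SNP genetic risk
score (GRS) for circulating 25-hydroxyvitamin D (25OHD), with a fully
calibrated synthetic-cohort generator for validation.

## Who this is for

Epidemiologists and biostatisticians who want a tested, reproducible
implementation of the classic "allele score → biomarker → survival
outcome" instrumented analysis: score construction from genotypes or
imputed dosages, the first-stage biomarker regression, age-adjusted Cox
proportional-hazards outcome models, and the scaled Wald-ratio causal
estimate with delta-method standard errors. Because individual-level
cohort data of this kind are rarely shareable, the package ships a
generator that emulates the full data structure — a cohort of ~23,000
women followed ~20 years with a measured-25OHD subcohort of ~1,800 —
with every simulation truth known, so each stage of the pipeline can be
validated by parameter recovery.

## The model

**Score.** For five SNPs in *DHCR7*, *CYP2R1* and *GC* (rs11234027,
rs12794714, rs10741657, rs7944926, rs2282679), the GRS sums counts
(0/1/2) of the allele associated with *higher* 25OHD, giving a score in
0–10; imputed dosages are hard-called by rounding to the nearest
genotype. A sensitivity variant excludes the *GC* SNP (range 0–8).
Categories 0–5 / 6–7 / 8–10 and non-splitting rank quintiles are
provided.

**First stage.** OLS on the measured subcohort:
`25OHD_i = α + β₂ · GRS_i + ε`, with R² and the single-predictor
F = R²(n−2)/(1−R²) as the instrument-strength index.

**Outcome stage.** Cox proportional hazards (Breslow ties, Newton–
Raphson on the partial likelihood, Efron behind a flag), adjusted for
baseline age (optionally BMI): `β₁` = log hazard ratio per score point.

**Causal estimate.** The Wald ratio scaled to 20 nmol/L of 25OHD:

    β_IV = 20 · β₁ / β₂,
    SE_IV² = (20/β₂)² SE₁² + (20 β₁/β₂²)² SE₂²   (delta method)

reported as `exp(β_IV)` with a 95% CI; a first-stage F below 10 flags a
weak instrument. A "simple" rescaling variant (multiply β₁ and SE₁ by
20/β₂, slope treated as known) is also provided, as is the Bonferroni
threshold α/m for the multiple-endpoint testing rule.

**Generator.** Hardy–Weinberg genotypes at configurable risk-allele
frequencies; 25OHD Normal with mean 67.8 and SD 26.1 nmol/L whose
score-explained variance is calibrated exactly to a target R² (default
2.6%, ≈2.85 nmol/L per allele); exponential event times per endpoint
(total cancer, breast, colorectal, lung, total death, cancer death)
with closed-form hazard calibration to target event counts, death
censoring incidence, and optional causal log-hazard effects of latent
25OHD.

## Worked example

Simulate a cohort in which higher 25OHD *causally increases* total
mortality with hazard ratio 1.30 per 20 nmol/L, then recover the effect:

```python
import numpy as np
import vitdmr as v

c = np.log(1.30) / 20          # per-nmol/L log hazard ratio
cfg = v.GeneratorConfig(
    causal_log_hr_per_nmol={"total_death": c, "cancer_death": c}
)
cohort = v.generate_cohort(cfg, seed=7)
model = v.MendelianRandomization.from_cohort(cohort)
print(model.fit("total_death").summary())
```

```
Mendelian randomization: total_death
==========================================================
exposure score: grs    adjusted for: age
cohort n = 23294, events = 3199; first-stage n = 1782
----------------------------------------------------------
First stage (25OHD ~ score):
  slope = 2.6735 nmol/L per point (SE 0.4223)
  R2 = 0.0220   F = 40.1
Cox outcome model (per score point):
  HR = 1.038 (1.014-1.063)   p = 0.00208   [breslow ties, converged=True]
Wald IV (delta) per 20 nmol/L 25OHD:
  ratio = 1.323 (1.085-1.613)   p = 0.00563
proportional-hazards check: min p = 0.576
==========================================================
```

Reading the output: the score explains 2.2% of 25OHD variance in this
replicate (F ≈ 40, a strong instrument); each score point raises the
mortality hazard by 3.8%; dividing by the 2.67 nmol/L-per-point first
stage and scaling by 20 returns a causal ratio of 1.32 (CI 1.09–1.61) —
recovering the simulated truth of 1.30 within sampling noise. Under a
null configuration (all causal coefficients zero, the default) the same
pipeline returns ratios scattered around 1.00.

A command-line interface wraps the same steps
(`vitdmr simulate|grs|associate|mr|report|run-all`); `run-all` writes a
report bundle with the per-endpoint continuous + category hazard-ratio
table, per-SNP associations, quintile 25OHD means with a trend test,
the IV table for both score variants, and a manifest with content
digests (same seed ⇒ byte-identical bundle).

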