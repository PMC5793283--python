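# Methods

## The analysis

The package implements a one-sample Mendelian-randomization (MR)
pipeline in which an unweighted allele-count genetic risk score (GRS)
for circulating 25-hydroxyvitamin D (25OHD) instruments the biomarker
against time-to-event cancer and mortality endpoints.

1. **Score.** Five SNPs (two in *DHCR7*, two in *CYP2R1*, one in *GC*)
   each contribute the count (0/1/2) of the allele associated with
   higher 25OHD, so the score spans 0–10. Imputed dosages in [0, 2] are
   hard-called by rounding to the nearest genotype; an exact half-way
   dosage (0.5 or 1.5) rounds away from zero. This tie rule is a
   convention — ties have probability zero for continuous dosages — and
   is documented rather than consequential. Values outside [0, 2] by
   more than 1e-8 are rejected. The *GC*-excluded sensitivity score
   (range 0–8) drops rs2282679. Categories use fixed cuts 0–5
   (reference), 6–7, 8–10.

2. **First stage.** OLS of measured 25OHD on the score over the
   subcohort with biomarker measurements. R² and the single-predictor
   F = R²(n−2)/(1−R²) are always reported for the exposure-only model;
   a covariate-adjusted slope is reported separately when requested.
   Instrument strength is indexed by F, with a weak-instrument flag
   below F = 10.

3. **Outcome stage.** Cox proportional hazards maximized by
   Newton–Raphson from β = 0 on the Breslow-ties partial likelihood

       l(β) = Σ_j [ s_jᵀβ − d_j · log Σ_{i∈R(t_j)} exp(x_iᵀβ) ],

   over distinct event times t_j with d_j tied events, s_j the sum of
   their covariates and R(t_j) the at-risk set. Efron's tie correction
   is available behind `ties="efron"`; the two coincide exactly on
   tie-free data. Standard errors come from the inverse observed
   information. Covariates are mean-centred internally (the partial
   likelihood is invariant, conditioning improves). Convergence is
   declared when the largest score component falls below 1e-8 or the
   log-likelihood gain below 1e-10, with at most 50 iterations and
   step-halving whenever a Newton step would decrease the likelihood.
   A monotone likelihood (perfect separation) is detected as a
   coefficient exceeding 10 per covariate SD and reported as
   `converged=False` rather than raised. The proportionality assumption
   is checked per term by correlating Schoenfeld residuals with the
   rank of event time, referring d·ρ² to χ²(1); with fewer than 3
   events the test is reported missing. 95% intervals use
   z = 1.959964 throughout.

4. **Causal estimate.** The Wald ratio scaled to 20 nmol/L,
   β_IV = 20·β₁/β₂, with the delta-method variance
   (20/β₂)²SE₁² + (20β₁/β₂²)²SE₂², treating the two stages as
   independent. The stages are estimated on nested samples (subcohort ⊂
   cohort); the independence approximation is the single-sample
   convention, and the dominant SE₁ term is unaffected by it. The
   "simple" variant multiplies β₁ and SE₁ by 20/β₂ with the slope
   treated as known; its SE is never larger than the delta SE (equality
   iff SE₂ = 0 or β₁ = 0). The outcome model is a hazard model, so the
   exponentiated estimate is a hazard-ratio-type quantity; the package
   labels it a ratio with the source model named rather than an odds
   ratio. The multiple-testing rule is plain Bonferroni α/m.

### Validity region of the delta-method SE

The delta formula is a first-order approximation. For the exact ratio
of two independent Gaussians the sampled SD exceeds it by roughly
1.5·(SE₂/β₂)² in relative terms when the numerator-variance term
dominates — about 3% at |β₂|/SE₂ = 7 and 6% at 5. Agreement within 1%
of a parametric bootstrap therefore requires |β₂|/SE₂ ≳ 12–17, not
merely > 5; the test suite documents both regimes. What matters for
inference — CI coverage and type-I error of the full pipeline at its
actual first-stage strength (F ≈ 40–50) — is verified directly by
simulation and is nominal within Monte-Carlo tolerance.

## The synthetic-cohort generator

The generator emulates the structure of a large prospective female
cohort: n = 23,294 followed 20 years, with a measured-25OHD subcohort
of n = 1,782 drawn as a simple random sample.

**Genotypes.** Independent Hardy–Weinberg columns: the risk-allele
count at SNP s is Binomial(2, p_s). At these five loci the
higher-25OHD allele is the *major* allele, so by default
p_s = 1 − MAF_s; the default MAFs (0.21, 0.42, 0.38, 0.40, 0.28) are
documented stand-ins inside the 16–44% range typical of European-
ancestry panels. This orientation gives a mean score ≈ 6.6 and
category shares ≈ 28% / 41% / 31%, matching the observed distribution
of such scores; `risk_is_minor=True` flips any SNP. Linkage
disequilibrium is not simulated even though SNP pairs share a gene —
the analysis treats the score as a plain sum, for which only Var(GRS)
matters, and Var(GRS) = Σ 2p(1−p) is LD-free by construction here.
Imputation is emulated by adding N(0, 0.1²) noise to the dosages of
the three imputed SNPs and clamping to [0, 2]; 0.1 dosage units
represents well-imputed common variants (the hard-call rounding then
mis-calls with probability ~1e-6), and is configurable.

**25OHD.** ohd_i = α + Σ_s b·count_is + N(0, σ²), with a shared
per-allele effect b solved from b²·Var(GRS) = R²·SD², and α, σ chosen
so the population mean and total SD equal 67.8 and 26.1 nmol/L. At the
default R² = 2.6% this gives b ≈ 2.85 nmol/L per allele. Negative
draws are clamped at 0 (≈0.5% of subjects at defaults; the fraction is
recorded on the cohort). The latent value drives the causal survival
mechanism for every subject; only subcohort members carry it as a
measured value.

**Survival.** Each endpoint's latent event time is exponential with
subject hazard λ_e · exp(c_e·(ohd−67.8) + γ_age·(age−54.7)), censored
administratively at 20 years. Mortality is decomposed into competing
cancer-death and other-death compartments (so cancer death implies
total death at the same time), and total cancer into competing
breast/colorectal/lung/other-site compartments (so a site event
implies a total-cancer event at the same time); incidence endpoints
are additionally censored at death. Each compartment carries its own
endpoint's causal coefficient c_e, so a proportional effect on
all-cause mortality is specified by setting `total_death` and
`cancer_death` together. γ_age defaults to 0 so the closed-form hazard
calibration is exact; the Cox models still adjust for age as the
analysis design prescribes.

**Hazard calibration.** Baseline rates are solved in closed form from
target event counts (defaults 3985 total cancer, 1560 breast, 329
colorectal, 330 lung, 2973 total deaths, 770 cancer deaths per 23,294
over 20 years): the death rate from n(1−e^{−λT}) = events; the
total-cancer rate from the death-competing form
λ_c/(λ_c+λ_d)·(1−e^{−(λ_c+λ_d)T}) = events/n (ignoring death
censoring would leave the observed cancer count ~6% short); site rates
as proportional shares of the total-cancer rate (sites compete with
each other, so shares make each expected site count exact); the
cancer-death rate as the death rate times the cancer-death share of
deaths. Targets are counts out of a reference size (23,294), so
scaling the simulated cohort down leaves all rates unchanged. The
plain single-risk calibrator is also exposed.

**Ages and BMI.** Age ~ Normal(54.7, 7.1) truncated below at 45; BMI ~
Normal(25.9, 5.0) truncated below at 15. Both use proper truncated
normals, not clipping.

**Determinism.** One `numpy` Generator seeded per run drives every
draw in a fixed order; identical (config, seed) reproduces the cohort
bit for bit, and the pipeline's report bundle is byte-identical across
reruns, with SHA-256 digests recorded in the manifest.

### What the generator does *not* emulate

Real measured-25OHD subgroups assembled from case–control substudies
are not random subcohorts; here the subcohort is a simple random
sample, so the first-stage slope needs no sampling correction. There
is no seasonal 25OHD variation, no LD, no genotyping error beyond the
Gaussian dosage noise, no competing-risks estimand beyond
cause-specific censoring, and baseline hazards are constant
(exponential) rather than age-increasing — γ_age is exposed but
defaults off. Passing recovery tests therefore validates the
*estimators* under the assumed data-generating process; they do not
certify behaviour under informative subcohort sampling or
non-proportional real-world hazards.

## Quintile assignment

Discrete scores make exact 20% bins impossible. Quintiles are assigned
by exhaustive search over non-splitting cut points (all subjects
sharing a score value stay together) minimizing Σ|bin − n/5|, with
ties between optimal cut sets resolved toward lower cut values. A
single distinct score yields one group with a warning rather than an
error. The 25OHD trend across quintiles is tested by OLS of 25OHD on
the quintile index (Wald p for zero slope).

## Problem sizes used in validation

The test suite and acceptance script size their simulations to the
study conditions: first-stage recovery averages 200 replicates at the
subcohort size (n = 1782); event calibration uses one full cohort
(n = 23,294); causal-effect recovery averages 100 replicates (full
size in the acceptance script; n = 8000 with a 1500 subcohort in the
test suite, which widens the Monte-Carlo band correspondingly);
null coverage/type-I use 500 replicates at n = 4000. Ratio estimates
are averaged on the log scale (geometric mean), the natural scale for
ratio estimators, which avoids the Jensen inflation an arithmetic mean
of ratios carries.

## Known limitations

- Single aggregate instrument only: no IVW/MR-Egger/weighted-median
  multi-instrument estimators, and no weighted GRS — both are
  documented extension points, deliberately out of scope.
- The Wald ratio carries the usual finite-sample ratio bias of order
  1/F (~2% at F ≈ 48), visible as a small upward shift in recovery
  simulations; it is a property of the estimator, not the code.
- No time-varying covariates, stratified baselines, frailty terms or
  Fine–Gray competing-risks models.
- The delta-method SE assumes independent stages; a delete-one
  jackknife over the subcohort can replace the model-based first-stage
  slope SE (`jackknife_first_stage=True`) for comparison, but the
  subcohort contributes only the minor second delta term, so the two
  rarely differ materially.
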