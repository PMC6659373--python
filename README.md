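# sleepmr

Linear and non-linear **Mendelian randomization (MR)** for studying the
causal effect of habitual sleep duration on cognitive outcomes
(reaction time, visual-memory errors, prospective cognitive decline,
dementia), together with a synthetic biobank-style cohort generator so
the entire analysis — instrument construction, split-sample two-sample
MR, pleiotropy sensitivity analyses and residual-stratified non-linear
MR — runs end-to-end without any restricted data.

It is aimed at genetic epidemiologists and methods researchers who want
a tested, reproducible reference implementation of this class of study:
every estimator is exercised against closed-form oracles and
Monte-Carlo calibration suites, and every pipeline stage is
deterministic under a single master seed.

## The statistical machinery

**Instruments.** k near-independent biallelic SNPs with per-allele
dosages g_ij ∈ [0, 2] under an additive model. Per-SNP
instrument–exposure (G-X) and instrument–outcome (G-Y) associations
(β̂_Xj, σ_Xj) and (β̂_Yj, σ_Yj) come from univariable linear or
logistic regressions. Joint instrument strength is summarised as
R² from the multivariable regression of exposure on all dosages, with
F = ((n − k − 1)/k) · R²/(1 − R²).

**Linear MR.** The Wald ratio per SNP is β̂_Yj / β̂_Xj. The main model
is the fixed-effect inverse-variance-weighted (IVW) estimator

    β̂_IVW = Σ_j w_j β̂_Xj β̂_Yj / Σ_j w_j β̂_Xj²,   w_j = 1/σ_Yj²,

equivalent to weighted least squares of β̂_Y on β̂_X through the
origin, with SE = (Σ w_j β̂_Xj²)^{−1/2}. Sensitivity estimators:
**MR-Egger** (the same weighted regression with a free intercept; a
non-zero intercept indicates directional horizontal pleiotropy) and the
**weighted median** (weighted 50th percentile of the ordered Wald
ratios, weights β̂_Xj²/σ_Yj², SE by seeded parametric bootstrap).
Winner's curse is mitigated by a split-sample design: the cohort is
randomly halved, G-X from one half is combined with G-Y from the other
(A-on-B and B-on-A) and the two estimates are pooled by fixed-effect
meta-analysis. Residual bias from sample overlap is quantified with the
approximation bias ≈ overlap × confounded association / F.

**Non-linear MR.** The sample is stratified on the *IV-free residual*
(exposure minus its genetic-score prediction, which avoids collider
bias from stratifying on the exposure itself). In each stratum the
localized average causal effect (LACE) is the ratio of the
score–outcome to the score–exposure regression slopes; the LACEs become
segment gradients of a continuity-constrained piecewise-linear
exposure–outcome curve anchored at a reference exposure. Non-linearity
is tested with Cochran's Q over the LACEs and an inverse-variance
meta-regression of LACE on stratum mean exposure (quadratic test).
Because self-reported sleep comes in whole hours, a Monte-Carlo
de-discretization harness re-runs the fit on uniformly jittered copies
of the exposure and aggregates.

**Synthetic cohorts.** `sleepmr.simdata` generates dosages, a discrete
exposure (mean 7.17 h/day, SD 1.07, range 2–12) whose SNP-explained
variance is calibrated to a target R² (default 0.65%), a latent
confounder driving exposure, covariates and outcomes, an optionally
asymmetric J-shaped dose-response with vertex at 7 h, horizontal
pleiotropy via direct SNP→outcome effects, log-normal reaction times,
Poisson visual-memory error counts, rare binary outcomes calibrated to
a requested prevalence, and repeated assessments with practice effects
and a declining subgroup for SRB-based decline classification.

## Worked example

```python
import numpy as np
from sleepmr import (CausalShape, OutcomeSpec, SimParams, default_snp_panel,
                     simulate_cohort, split_sample, snp_associations,
                     harmonize, ivw, meta_fixed, exponentiate_report, strength)

panel = default_snp_panel(k=77, seed=0, effect_dist="shifted_exponential")
params = SimParams(
    n=100_000, snps=panel, seed=42, target_r2=0.0065,
    causal_shape=CausalShape("linear", beta1=np.log(1.01)),  # 1%/h slower RT
    confounder_effect_x=0.3, confounder_effect_y=0.04,
    outcomes=(OutcomeSpec("rt_ms", "lognormal", 549.0, noise_sd=0.2),),
)
cohort = simulate_cohort(params)
rep = strength(cohort.sleep_hours, cohort.dosages)
print(f"instrument strength: R2 = {rep.r2_percent:.2f}%, F = {rep.f_stat:.2f}")

G = cohort.dosages.to_numpy()
sleep = cohort.sleep_hours.astype(float)
log_rt = np.log(cohort.pheno["rt_ms"].to_numpy())
ia, ib = split_sample(cohort, seed=7)
ests = []
for ix, iy in ((ia, ib), (ib, ia)):
    gx = snp_associations(G[ix], sleep[ix], "linear", cohort.specs)
    gy = snp_associations(G[iy], log_rt[iy], "linear", cohort.specs)
    ests.append(ivw(harmonize(gx, gy)))
meta = meta_fixed(ests)
out = exponentiate_report(meta)
print(f"meta-IVW: beta = {meta.beta:.4f} per hour/day, p = {meta.p:.3f}")
print(f"Exp(beta) = {out['exp_beta']:.3f} "
      f"(95% CI {out['exp_lcl']:.3f}-{out['exp_ucl']:.3f}) "
      f"-> {out['percent_text']} slower reaction time")
```

Output:

```
instrument strength: R2 = 0.69%, F = 8.95
meta-IVW: beta = 0.0077 per hour/day, p = 0.254
Exp(beta) = 1.008 (95% CI 0.994-1.021) -> 1% slower reaction time
```

The cohort was generated with a true 1%-per-hour multiplicative effect
on reaction time; the split-sample meta-analysed IVW estimate
recovers Exp(β) ≈ 1.01 (the wide CI reflects that 77 weak instruments
explain only ~0.7% of exposure variance at n = 100 000 — the F
statistic scales with n, reaching ~34 at the emulated full cohort
size of 395 803).

A full study replica — descriptive tables, observational regressions,
split-sample linear MR for five outcomes, an external two-sample arm
and non-linear MR — runs from one config:

```bash
sleepmr run --config study.yaml --out results/   # or: python -m sleepmr.cli
```

with subcommands `simulate`, `derive-assoc`, `mr` and `nlmr` operating
on each other's CSV/TSV artifacts.

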