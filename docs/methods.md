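# Methods

This note documents the models implemented in `sleepmr`, the defaults
of the synthetic-data generator, the numerical conventions, and the
design of the Monte-Carlo suites, in enough detail to reproduce or
deliberately deviate from any of them.

## Causal model and estimands

The exposure X is habitual sleep duration in hours/day, observed as an
integer (self-report granularity). Outcomes Y are analysed on a log or
log-odds link scale: ln(reaction time in ms), ln(visual-memory errors
+ 1), and binary outcomes (SRB-defined decline, dementia). Genetic
instruments G_j are biallelic dosages under an additive model,
assumed (i) associated with X, (ii) independent of the confounder U,
and (iii) affecting Y only through X except where horizontal pleiotropy
is explicitly simulated.

Linear MR targets the per-hour slope β in E[Y | do(X)] = α + βX on the
link scale; exponentiation turns it into a multiplicative effect
(Exp(β) = 1.03 on reaction time reads as "3% slower per extra hour").
Non-linear MR targets the local derivative of the dose-response curve:
the LACE in stratum k estimates f'(x) near the stratum's mean exposure.

## Estimators and numerical conventions

* **Per-SNP associations** are univariable regressions. The linear
  case is evaluated in closed form (column-vectorised sums, residual
  df = n − 2); the logistic case is a two-parameter Newton/IRLS sweep
  vectorised across SNPs with non-converged or separated columns
  flagged non-estimable and dropped from summary tables. Both routes
  are verified against statsmodels OLS/Logit in the unit suite.
* **Wald ratio**: β̂_Y/β̂_X with the first-order SE σ_Y/|β̂_X|. No
  second-order term; instrument-exposure uncertainty is not propagated
  into IVW weights. This matches the fixed-effect IVW convention.
* **IVW**: weights 1/σ_Yj², fixed-effect; SE = (Σ w β̂_X²)^{−1/2}.
* **MR-Egger**: instruments oriented so β̂_X ≥ 0 (outcome association
  flipped with it), then weighted least squares with free intercept.
  SEs come from the fixed-weight information matrix inv(X'WX), i.e.
  no residual-overdispersion rescaling, consistent with the
  fixed-effect choice for IVW. Fewer than 3 instruments, or zero
  spread in β̂_X, is refused.
* **Weighted median**: ratios ordered (stable sort), weights
  β̂_X²/σ_Y², cumulative percentiles p_j = (S_j − w_j/2)/S_total,
  linear interpolation at p = 0.5. SE from a parametric bootstrap
  (default 1000 draws of β̂_X* ~ N(β̂_X, σ_X), β̂_Y* ~ N(β̂_Y, σ_Y),
  seeded). Zero-β̂_X instruments are dropped with a note.
* **Meta-analysis**: fixed-effect inverse-variance pooling of the
  A-on-B and B-on-A split estimates; a single estimate is passed
  through with a warning note.
* **Sample-overlap bias**: bias ≈ overlap_fraction × confounded
  observational association / F, the first-order approximation; the
  optional type-I rate is the normal rejection probability of an
  estimator shifted by bias/SE. The exact finite-sample variant is a
  known refinement and deliberately out of scope.
* **Harmonization**: outcome-side alleles are aligned to the exposure
  side; swapped orientation flips the outcome beta, strand-complement
  codings are matched the same way (unambiguous for non-palindromic
  SNPs), palindromic (A/T, C/G) SNPs with exposure-side EAF inside
  [0.42, 0.58] are excluded as ambiguous (the window is a convention
  and is parameterised), and resolvable palindromic SNPs are oriented
  by allele-frequency side. Every input SNP lands either in the
  aligned table or in the exclusion log with a reason.
* **CIs and p-values**: estimate ± 1.96·SE and two-sided normal tails
  throughout; binary-outcome estimation stays on the log-odds scale
  with exponentiation only at reporting.

### Non-linear MR choices

* The instrument for stratified estimation is a single genetic score
  (per-SNP stratified MR is hopelessly underpowered at realistic
  instrument strength). The pipeline uses the score weighted by
  full-sample per-SNP G-X estimates; an unweighted score is available
  and is the default for the confounder screen, which mirrors the
  "sum of dosages" construction.
* Stratification uses quantiles of the IV-free residual with stable
  tie-breaking, q = 3 by default (10 for the de-discretized
  sensitivity run), minimum stratum size 100 — smaller strata are
  flagged non-estimable rather than silently fitted.
* The LACE denominator (score→exposure slope) is stratum-specific by
  default; a full-sample-denominator option exists because the choice
  is genuinely open — stratum-specific is self-consistent with the
  first-order SE used here.
* Stratum exposure ranges for the piecewise curve are overall exposure
  quantile boundaries, which are contiguous by construction; residual
  strata overlap in raw exposure, so observed min/max would not be.
  The curve integrates the LACE gradients over these ranges and is
  shifted so its value at the reference exposure (mean sleep) is zero;
  continuity at the knots is exact by construction (checked to 1e-12).
* De-discretization adds uniform(−w/2, w/2) jitter with w = 1 reporting
  unit, repeats the full fit (default 100 times; 50 in the pipeline
  default to keep run time modest), and aggregates by the mean of
  stratum LACEs and the median of test p-values. The jitter law and
  repeat count are implementation choices, documented rather than
  claimed.

### SRB decline classification

Follow-up scores are regressed on baseline over complete pairs (the
method admits covariates; the default is baseline-only with an optional
covariate hook) and z = residual / residual SD (df = n − p) defines a
case beyond a one-sided threshold in the worsening direction (more
errors / slower = higher is worse). The threshold defaults to 1.645
(~5% expected case rate under stability); it is a parameter because no
canonical value exists.

## The synthetic-data generator

`simdata` emulates the *structure* of a large mid-life population
biobank, with defaults fixed once (collected in `EMULATION_TARGETS`):

| parameter | default | unit / rationale |
|---|---|---|
| n (full scale) | 395 803 | emulated cohort size |
| instruments k | 77 | near-independent SNPs |
| EAF | U(0.1, 0.9) | common variants, no LD (non-goal) |
| effect magnitudes | Exp(1), oriented positive | GWAS-like heavy tail; `shifted_exponential` (1+Exp(1)) bounds strength away from zero; `constant` for homogeneous panels |
| target R² | 0.65% | joint SNP-explained exposure variance; per-SNP effects rescaled to hit it exactly in expectation |
| exposure | mean 7.17, SD 1.07, integers 2–12 h/day | latent Gaussian, rounded then clamped *before* outcome generation, so the measured self-report drives outcomes |
| dose-response | quadratic, vertex 7 h, β₁ = 0.01, β₂ = 0.006 (short side) / 0.012 (long side) per h² | asymmetric J, steeper long-sleep arm, magnitudes matched to the observational effect sizes being emulated |
| confounder U | standard normal | one latent composite suffices to induce confounding; effects 0.3 h/SD on exposure, 0.04 log-units/SD on outcomes |
| covariates | age, sex, deprivation, BMI, comorbidity | noisy functions of U (sex independent), so adjustment and the score–confounder screen have realistic structure |
| visual memory | Poisson, rate 4.0 at vertex, lognormal overdispersion SD 0.5 | count of matching errors, log link |
| reaction time | lognormal, median 549 ms, SD 0.2, effect scale 0.4 | RT responds proportionally less than VM |
| dementia | Bernoulli, prevalence 0.43%, effect scale 3.0 | logistic link, intercept calibrated by root-finding to the requested prevalence |
| follow-up | practice shift 0.10, decline fraction 4%, decline shift 0.9, extra noise SD 0.25 (all scaled by the outcome's effect scale) | repeated assessments that drift and contain a genuinely declining subgroup |

Pleiotropy enters as direct per-allele SNP→outcome effects added
outside the effect-scale multiplier; balanced (mean 0) and directional
(non-zero mean) regimes are both one panel parameter away.

All randomness derives from one master seed via `SeedSequence`
spawning; identical parameters reproduce cohorts bit-for-bit, and the
pipeline's artifacts are byte-identical across reruns of the same seed.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: linkage disequilibrium and proxy
instruments, genotyping error and imputation, population
stratification, selection/response bias, item-level cognitive-test
psychometrics, time-varying exposure, and code-list imperfection in
hospital records (the code-list matcher is exercised on synthetic code
tables). One further scale subtlety is intentional: the generator
parameterises count outcomes on the log-rate scale, while the analysis
(like the emulated study) models ln(errors + 1); for counts of mean ~4
with the default overdispersion the chain rule gives an attenuation
factor of ~0.83, so a 3%-per-hour log-rate truth appears as ~2.5%/h on
the analysis scale — visible in the acceptance report's visual-memory
estimate.

## Design of the Monte-Carlo suites

These are fixed simulation designs, sized by a priori power analysis;
the problem sizes below are the package's chosen validation scale.

* **Parameter recovery** (split-sample meta-IVW, 200 replicates,
  n = 20 000, 50 SNPs, true β = 0.05): run in a strong-instrument
  regime, target R² = 0.4, giving per-half per-SNP F ≈ 50. This is an
  estimator-validation design, not a cohort emulation: fixed-effect
  two-sample IVW carries a known regression-dilution factor ≈
  F̄/(F̄+1) from instrument-exposure estimation noise, so at the
  cohort-realistic 0.65% R² and desk-scale n the deterministic ~5–40%
  attenuation would dominate a mean-bias check. At F̄ ≈ 50 the residual
  dilution (≈0.1% of β) sits well inside Monte-Carlo noise, and the
  check verifies the estimator plus 95% CI coverage in [0.92, 0.98].
* **Directional pleiotropy** (200 replicates, same scale): constant
  per-allele direct effect +0.01 on the outcome, so the InSIDE
  assumption holds exactly and the true Egger intercept is 0.01. The
  panel uses `shifted_exponential` magnitudes: spread is needed for
  Egger identification, but a first run with plain exponential
  magnitudes showed that instruments with |β̂_X| within ~2 SE of zero
  get their estimated orientation flipped, turning constant pleiotropy
  into sign-mixed pleiotropy and biasing the Egger slope upward —
  bounding every instrument's strength away from zero restores the
  scenario's stated premise. IVW is verified to be materially biased
  while the Egger slope and intercept centre on their targets.
* **Non-linearity calibration**: the type-I runs use a linear truth at
  n = 20 000 (Cochran-Q and quadratic-test rejection in [0.03, 0.08]
  at nominal 0.05). The power run uses n = 50 000 with an amplified
  asymmetric J (β₂ = 0.015/0.03): the default, cohort-realistic
  curvature only reaches quadratic-test z ≈ 5–6 at n ≈ 4×10⁵, so the
  calibration effect size is scaled to keep power > 0.8 detectable at
  validation scale while preserving the long-arm-steeper geometry used
  for the LACE-ordering check.

## Known limitations

* Fixed-effect SEs everywhere: under real heterogeneity the IVW and
  Egger CIs are anti-conservative (multiplicative random-effects
  scaling is a non-goal here).
* First-order ratio SEs ignore denominator uncertainty; with weak
  per-stratum instruments LACE SEs are slightly optimistic.
* The two-sample weak-instrument dilution discussed above applies to
  the split-sample design itself; at the emulated full scale (F ≈ 34)
  it attenuates estimates by ~3–6%, which is visible when comparing
  recovered Exp(β) to the generating truth.
* The logistic IRLS flags but does not rescue separated SNPs; with
  very rare outcomes in small strata per-SNP G-Y tables can lose rows
  (always logged through the harmonization exclusion log).
* `dediscretized_nonlinear` aggregates SEs as the mean of per-jitter
  SEs, ignoring between-jitter variance (small for width 1, but a
  simplification).
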