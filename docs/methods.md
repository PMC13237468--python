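# Methods

## The estimation problem

A binary health behaviour (menstrual hygiene management, MHM) is
endogenous to a count health outcome (children ever born, CEB): unobserved
factors — social norms and exclusion around menstruation — plausibly drive
both the behaviour and fertility. A naive Poisson regression of CEB on MHM
is therefore biased. The package implements the two-stage residual
inclusion (2SRI) control-function estimator for this setting, with
household WASH availability (water source location, handwashing place,
hand cleanser) as excluded instruments: WASH shifts the cost of practising
menstrual hygiene but has no direct pathway to fertility conditional on
the socio-economic controls.

### Structural model and assumptions

* Selection: `MHM = 1[x'α + ε ≥ 0]`, `ε ~ N(0,1)`; probit first stage.
* Outcome: Poisson with log-mean `x1'β + γ·MHM + e`.
* Endogeneity: `E[e | ε] = δ·ε` (linear conditional expectation — exact
  under joint normality); `(e, ε)` independent of `x`.
* Exclusion: the WASH dummies enter `x` but not `x1`.

Under these assumptions the conditional mean of the outcome given the
realized treatment is, by truncated-normal algebra,

```
E[CEB | x, MHM=1] = exp(x1'β + γ + δ²/2) · Φ(x'α + δ)/Φ(x'α)
E[CEB | x, MHM=0] = exp(x1'β     + δ²/2) · Φ(−x'α − δ)/Φ(−x'α)
```

implemented exactly in `oracle_conditional_mean` (via log-CDF
differences). The 2SRI second stage replaces the intractable term with the
first-order plug-in `exp(δ·m̂)`, where `m̂` is the probit generalized
residual `m̂ = MHM·μ(x'α̂) − (1−MHM)·μ(−x'α̂)`, `μ = φ/Φ`. The
approximation error is `O(δ²)`; the test suite verifies that the gap to
the exact oracle shrinks monotonically over `δ ∈ {0.6, 0.3, 0.1, 0}` and
that at `δ = 0.3`, n = 20,000, the 2SRI estimate of γ is closer to the
truth than the naive estimate in ≈100% of 200 replicates (the naive bias
there is ≈0.49 against γ = 0.05).

### Inference

The second stage contains a generated regressor, so model-based standard
errors understate uncertainty for every coefficient except the residual's
own under the null. Two covariances are reported:

* **Pairs bootstrap** (default 500 replicates, configurable): rows are
  resampled with replacement and *both* stages re-run per replicate;
  coefficient spread gives the covariance, and percentile CIs are stored
  alongside normal-approximation ones. Replicates that fail to fit are
  logged and dropped; a failure rate above 10% aborts.
* **Model-based** covariance, kept because the z-test on the residual
  coefficient δ̂ is asymptotically valid with it *under the null of
  exogeneity* (the standard two-step endogeneity test). Its empirical size
  is 4–6% at the 5% level across seeds (400 replicates, n = 5,000).

## The synthetic survey generator

The generator emulates the structure of a MICS-type women's-questionnaire
extract: one row per ever-married woman aged 15–49 with socio-demographics,
household-head attributes, media/ICT exposure, contraception and
nicotine/alcohol indicators, raw WASH facility indicators plus the derived
5-category WASH variable, the three menstrual-hygiene questionnaire items,
and two fertility counts (children ever born; total live births as an
independent re-draw from the same conditional mean). Hidden ground-truth
columns (latent ε, linear indices, true conditional mean) are split into a
`.truth.csv` sidecar and never reach the estimation stages.

Default parameters reproduce the survey's published marginals: WASH
category shares (2, 23.7, 9.5, 42, 23)% (renormalized — they sum to
100.2% as printed), education (29, 35, 36)%, wealth (40, 20, 40)% sampled
at quintile granularity consistent with the three-category recode, media
exposure 78%, contraception non-use 38%, nicotine/alcohol 75%, 5% missing
MHM, n = 4,989. Quantities the source survey does not publish were fixed
once at realistic values for the region: rural share 0.60, female-headed
households 0.25, head age uniform 20–80, five generic region and ethnicity
levels. The selection coefficients are calibrated so the simulated MHM
share is ≈63% and the WASH average marginal effects span ≈0.31–0.53
probability points; the outcome intercept gives a mean parity ≈2.9
(a published table lists a mean "fertility rate" of 0.40, which is not a
credible children-ever-born mean for this population; the outcome level is
therefore configurable and defaults to a realistic parity). Defaults:
γ = 0.05, δ = 0.3.

Design choices:

* Covariates are sampled independently (only marginals are published); an
  optional one-factor Gaussian copula (`copula_rho`) can induce
  correlation, off by default.
* Missingness is MCAR on the MHM indicator (mechanism unstated in the
  source; MCAR is the neutral choice) and also blanks the materials item.
* Random streams are split per stage (covariates / selection / outcome /
  missingness) via seed sequences, so toggling one stage never perturbs
  another.
* The questionnaire items are emitted consistently with the latent
  indicator: all-yes exactly when MHM = 1.
* **Head age is causally inert in both equations by default.** This is
  deliberate: the household-head age serves as the placebo outcome, and a
  placebo must be independent of (ε, MHM) for its null to be true. See
  the placebo section for why even a spurious estimated coefficient on
  the placebo variable contaminates the control function.
* An overflow guard rejects configurations whose realized Poisson
  log-mean exceeds 20.

What passing tests on this generator do **not** show about real data:
cluster sampling and design weights are not emulated (each row is i.i.d.),
covariate dependence is absent by default, missingness is never
informative, and the linear-index/joint-normal selection model is exactly
true in simulation whereas it is an approximation in the field.

## Data preparation

* MHM indicator: 1 iff all three questionnaire items (privacy to wash and
  change, use of materials, reusable materials) are "yes"; any missing
  item propagates to missing. The rule is monotone in each answer.
* Eligibility filters in fixed order (marital → hysterectomy → menopause →
  age 15–49) with per-rule drop counts; idempotent.
* Wealth: quintiles collapse to rich (rich & richest), middle, poor
  (poor & poorest); unseen levels are errors, never dropped.
* WASH: five categories from the raw indicators, reference "none";
  contradictory combinations (water both at dwelling and elsewhere; wash
  facilities without any water source) raise.
* Missing MHM is regression-imputed: a probit of observed MHM on
  dwelling-water availability and the wealth dummies; the default
  deterministic policy thresholds the predicted probability at 0.5
  (mirroring a single imputed analysis dataset), a seeded Bernoulli
  policy is available for sensitivity. Perfect separation (detected by a
  strict index split between classes) falls back to a ridge-penalized fit
  with a warning. Rows missing any non-MHM analysis variable are
  listwise-deleted with an audit count.

## First stage and marginal effects

The probit is fitted by Newton iterations (statsmodels) from a zero start,
tolerance 1e-10, max 100 iterations; non-convergence is flagged, never
silent. Rank-deficient designs raise with the collinear columns named;
diverging coefficients raise a separation error. The sandwich covariance
is used for reporting, the observed-information covariance for the delta
method. Reference categories: WASH "none", wealth "rich", education and
head education "secondary+". Marginal effects follow the reporting
convention for factor variables: continuous covariates get
`mean(φ(x'α̂))·α̂_j`; each factor level gets the average discrete change in
`Φ` from the base level; standard errors by the delta method with a
central-difference Jacobian.

Numerical notes: the inverse Mills ratio is computed as
`exp(log φ − log Φ)`, accurate and finite over |z| ≤ 40; indices beyond
±40 are clamped with a warning (μ(−40) ≈ 40.02, μ(40) underflows to 0 —
nothing of statistical relevance lives outside the window). At the MLE
with an intercept the generalized residuals sum to zero by the score
equations; this identity is asserted at 1e-6·n in the tests and is a
useful end-to-end check of both stages.

## Second stage families

* **Poisson** (baseline): GLM with log link, IRLS tolerance 1e-12. The
  intercept score equation forces fitted means to reproduce the outcome
  total (asserted at 1e-6 relative).
* **NB2** (sensitivity, alternative outcome "total live births"):
  `var = μ + αμ²`, fitted on the BFGS log-α parameterization so α ≥ 0; a
  boundary-corrected likelihood-ratio equidispersion test uses the ½·χ²(1)
  mixture. On Poisson data α̂ < 0.01 and the hessian can be singular at
  the boundary, in which case the mean-parameter covariance falls back to
  the nested Poisson covariance (logged).
* **OLS** (placebo only): HC1-robust least squares.

Effects are reported as `(e^β − 1)·100` percentage changes, rounded to one
decimal in tables (coefficients to three).

## Instrument diagnostics

The diagnostics are defined for the linear IV regression, so they are
computed on a 2SLS of the outcome with the WASH dummies as excluded
instruments — the conventional companion output to a control-function
count model. Exogenous controls are partialled out (Frisch–Waugh) before
any rank computation; robust covariances carry an (n − k) adjustment.

* **KP rk LM** (under-identification): robust score test of a zero
  reduced-form coefficient vector, moments and variance evaluated under
  the rank-zero null; df = L. Under i.i.d. homoskedasticity it coincides
  with the Anderson canonical-correlation statistic n·R² in the
  weak-signal regime (they share the same null variance); under a strong
  first stage the two constructions diverge by a fourth-moment factor
  while both reject overwhelmingly. Empirical null size 4–6.5%.
* **KP rk Wald F**: robust Wald form divided by L; equals the squared
  robust first-stage t when L = 1 and tracks the classical first-stage F
  within a few percent on homoskedastic data.
* **Cragg–Donald F**: the classical (non-robust) first-stage F, for
  comparison against the Stock–Yogo table.
* **Hansen J**: two-step efficient GMM over-identification statistic,
  df = L − 1; just-identified models return (0, 0, n/a). With forced
  homoskedastic weighting it collapses exactly to the Sargan n·R²
  statistic. Empirical null size 4–5.5%.
* **Stock–Yogo**: embedded table of 10% maximal-relative-bias critical
  values for one endogenous regressor and 3–10 instruments (e.g. 10.27 at
  L = 4); untabulated keys raise rather than extrapolate.

Degrees of freedom are asserted from the declared roles, never inferred
from matrix shapes. All four statistics are invariant to rescaling any
instrument column.

## Placebo test and a contamination pitfall

The falsification harness swaps the outcome for household-head age and
re-runs CF-OLS (with the generalized residual), IV-2SLS and the full
diagnostics; verdict flags (`exclusion_supported`: MHM coefficient CI
covers 0; `endogeneity_ruled_out`: residual term non-significant) are pure
functions of the stored statistics at a configurable level (default 5%).

Implementation finding worth knowing: **the placebo outcome must be
excluded from the first-stage design, not just the outcome equation.** If
the placebo variable sits in the probit index, the generalized residual is
a deterministic, invertible function of it given the other covariates —
and because the relationship is exact rather than noisy, even a pure
noise-level estimated coefficient (true coefficient zero) lets the placebo
regression reconstruct the outcome through m̂, manufacturing z-statistics
up to ≈12 in simulation. `run_placebo` therefore drops any control that is
an affine transform of the placebo outcome from *both* stages; the first
stage is byte-identical to a main-pipeline probit on that pruned
specification, so the outcome swap itself still cannot move it. With this
design the placebo verdicts are clean in ≈95% of replicates, as a true
null demands.

Subsample runners (defaults: rural residents; ages 15–29) re-run the full
2SRI pipeline and diagnostics on filtered rows without mutating the parent
table, require ≥500 rows and both exposure classes, and drop controls that
collapse to a single level inside the stratum (they are absorbed by the
intercept). Heterogeneity is reported descriptively side by side; no
interaction test is performed.

## Monte-Carlo problem sizes

The validation studies run at: treatment-effect recovery — 200 replicates
at n = 20,000 for δ ∈ {0, 0.3}; endogeneity-test size — 400 replicates at
n = 5,000 (the scale of the motivating survey); diagnostics null
calibration — 400 replicates at n = 500 per test. Estimator studies set
`missing_rate = 0` to isolate the estimator from the separately-tested
imputation stage. All studies derive per-replicate seeds from a single
seed via seed sequences.

## Known limitations

* The 2SRI plug-in is first-order in δ; at large |δ| the residual bias in
  γ̂ grows (visible in the oracle-gap test).
* Survey design features (clusters, strata, weights) are out of scope; all
  inference treats rows as independent.
* The endogeneity z-test uses the model-based covariance and is only
  valid under the null; bootstrap CIs should be used for the residual
  coefficient when δ ≠ 0 matters.
* Stock–Yogo critical values are tabulated constants, not recomputed.
* The NB2 stage offers no NB1 variant, and the first stage is probit only.
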