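# Methods

## Data-generating model

Each virtual patient receives 100 mg of drug every 12 h as a 30-min IV
infusion, 12 doses in total, and contributes two plasma samples: 1 h after
the sixth dose (t = 61 h) and 11.5 h after the twelfth (t = 143.5 h).
Concentrations follow the analytic 1-compartment infusion superposition
solution with elimination rate k = CL/V1.  Individual clearance is

    CL_i = theta_CL * exp(theta_cov * (cov_i - cov_mean)) * exp(eta_i),
    eta_i ~ N(0, omega2_CL),

and observations carry one independent proportional error each,
Y = f * (1 + eps), eps ~ N(0, sigma_prop^2).  Defaults: theta_CL = 18 L/h,
V1 = 400 L, omega2_CL = 0.1, sigma_prop = 0.15 (15% CV).  No inter-occasion
variability; covariates are constant within subject.

Three covariates are drawn per subject from a multivariate normal: the true
covariate COVI (mean 70), its companion COVII (mean 50, sd 15) correlated
with COVI at a configurable 0–90%, and an independent noise covariate COVIII
(mean 5, sd 2).  COVI's sd is calibrated so that the weakest studied effect,
theta_cov = 0.026, produces +22% clearance at the covariate's 95th
percentile: sd = ln(1.22) / (0.026 * z_0.95) ≈ 4.65.  The three effect sizes
0.026 / 0.032 / 0.045 then span −18/+22%, −22/+27% and −29/+41% at the
5th–95th percentiles.  Dichotomous covariates (the categorical study
variant) are produced by thresholding a latent normal coordinate at the
quantile matching the prevalence, so a latent-scale correlation to a
continuous covariate is well defined; the variant applies a fractional CL
effect (1 + theta_frac * I) and adds an independent random effect on V1
(default variance 0.1).

Seeding: replicate r of a cell uses `SeedSequence(base_seed + r)` with four
spawned substreams (covariates, residual/IIV draws, fit-retry jitter, SIR),
so both selection engines see the identical dataset and results are
independent of execution order and worker count.

## FOCE+I estimation

The marginal likelihood is approximated by first-order conditional
estimation with interaction.  For subject i with observations y_i and
prediction f_i(eta):

1. find the conditional mode `eta_hat_i` of the penalized objective
   `sum_j [ r_j^2 / R_j(eta) + log R_j(eta) ] + eta' Omega^-1 eta` with
   R_j = sigma^2 f_j(eta)^2;
2. linearize f in eta at the mode with gradient G_i and accumulate

       OFV_i = log|V_i| + res_i' V_i^-1 res_i,
       V_i   = G_i Omega G_i' + diag(sigma^2 f_i(eta_hat)^2),
       res_i = y_i - f_i(eta_hat) + G_i eta_hat.

The total OFV is −2 times the approximate log-likelihood in the NONMEM
convention, i.e. the constant `n_obs * log(2*pi)` is omitted; only OFV
differences enter any selection decision.  The inner problem is solved by an
exact damped Newton iteration (analytic first and second derivatives of the
concentration in CL) for the scalar-eta model, warm-started from the
previous evaluation's modes; the tolerance (Newton step < 1e-9 on the eta
scale) makes the OFV path-independent to ~1e-12.  The outer problem runs
L-BFGS-B on log-transformed scale/variance parameters with finite-difference
gradients; failures are retried up to three times from multiplicatively
jittered (U(0.9, 1.1)) starting values.  The estimate covariance is
2 H^-1 from a central-difference Hessian at the optimum, delta-transformed
to the natural scale.  A general (pure-numpy) FOCE path accepting arbitrary
per-subject prediction/variance functions serves as the reference
implementation; the numba kernel is cross-checked against it and against an
adaptive Gauss–Hermite quadrature oracle in the test-suite.

Unconverged replicates are excluded from every downstream metric denominator
(and counted); in practice the retry scheme converges essentially always on
this well-specified simulation model.

## SCM

Candidate relations default to the three covariates on CL, exponential and
mean-centered at the dataset's sample mean (so fitted coefficients are
directly comparable to theta_cov); dichotomous candidates use the fractional
form.  Forward steps fit each remaining candidate singly and add the one
with the largest dOFV above chi2(1, forward_p); ties break by candidate
order; a candidate whose fit fails is treated as non-significant for that
step.  Backward elimination refits each reduced model and removes the
relation whose removal costs least, while that cost is below
chi2(1, backward_p); it repeats to stability.  Scenario settings: mode 1
forward p<0.05 / backward p<0.01 (common practice), mode 2 forward-only
p<0.1 (statistical head-to-head with the 90% CI criterion of frem_posthoc).
Fits are cached per relation-set, and the decision trace (step, candidate,
dOFV, threshold, decision) is retained for exact replay.

## FREM and its marginalization

FREM adds one pseudo-observation per covariate per subject,
`cov_obs = mu_k + eta_cov_k + eps_k`, with sd(eps_k) fixed at
1e-4 * sd(cov_k) — never estimated — and a full Omega over
(eta_CL, eta_cov).  Because the covariate block is linear-Gaussian, the
joint likelihood factorizes exactly into (i) the closed-form multivariate
normal likelihood of the covariates and (ii) the PK likelihood with the
eta_CL prior conditioned on the observed covariates.  The conditional prior
mean is linear in the centered covariates, so block (ii) is *identical* to a
full fixed-effects model: every covariate on CL with regression coefficients
b = S^-1 c and conditional IIV v = omega2 - c' S^-1 c (S the covariate
covariance, c the cross-covariances).  The covariate-block MLE is the sample
moments, which profile out exactly; `fit_frem` therefore fits the 7-
parameter FFEM by FOCE+I and reconstructs Omega as

    omega2_CL = v + b' S b,   c = S b,   coef_k = (S b)_k / S_kk.

A test asserts the marginal OFV equals the joint (covariates-as-
observations, 4-dimensional eta) FOCE objective to 1e-6 relative on random
instances.  Reported effect ranges are fractional CL changes at the
covariate's empirical 5th/95th percentiles.

## SIR and frem_posthoc

Uncertainty is single-pass sampling importance resampling: 1000 draws from a
multivariate-normal proposal centered at the estimates with the estimate
covariance (PK block from the fit Hessian; covariate-moment block from an
analytic-likelihood Hessian; the two are independent), importance weights
`exp(-(OFV - OFV_min)/2) / proposal density`, and 500 resamples without
replacement.  The 90% CI of each univariate coefficient is the 5th/95th
percentile of the coefficient recomputed from every resampled parameter
vector (so it reflects uncertainty in both the regression coefficients and
the covariate covariance).  Effective sample sizes below 10% of the draws
are flagged; the CI is still returned (small-n FREM fits routinely sit in
this regime, one reason SIR CIs can be narrow and the posthoc type-I error
inflated).  `frem_posthoc` retains covariates whose CI excludes zero and
reports the retained covariate with the largest effect size, ranked by the
larger absolute endpoint of the 5th–95th percentile effect range; the power
event for the true covariate requires both retention and largest effect.

## Evaluation metrics

Over R converged replicates: power = % with the selection event;
rbias = mean relative error and rrmse = root-mean-square relative error of
the true-covariate coefficient over the *qualifying* replicates only
(selection event for scm/frem_posthoc, all converged for the no-selection
frem_all view) — the denominator N differs by method and scenario by
construction; predictive fraction = % of qualifying coefficients strictly
inside (0, 2*theta_cov), i.e. |(est - true)/true| < 1 with a strict
boundary; type-I error = % flagging the noise covariate (forward-model
inclusion for scm, CI-excludes-zero for frem_posthoc).  Empty denominators
are reported as missing, never as zero.  COVII inclusion frequency is
carried as an extra column.

## Problem sizes

The full study design is 1000 replicates per cell; the default
`ScenarioConfig.replicates` is 1000 with overrides everywhere.  The bundled
acceptance recomputation uses 150-200 replicates for scm-based quantities,
100 for FREM+SIR-based quantities and 10 per n=500 cell; the test-suite's
calibration and monotonicity checks use 80–150 replicates.  At these sizes
binomial Monte-Carlo noise is ±3–5 percentage points on a power value.

## Numerical choices and degenerate inputs

Variance and scale parameters are optimized on the log scale with bounds
[e^-12, e^12]; non-finite objectives are mapped to a large finite penalty so
line searches backtrack instead of stalling.  Predictions below 1e-12 mg/L
(10 orders below the observed scale) are rejected inside the inner
optimization.  Designs with observations at t <= 0 are refused (zero
prediction makes the proportional error undefined), as are constant
covariates in FREM (singular covariate block), fractional effects driving
CL <= 0, and correlation outside [0, 1).  If a SIR percentile interval
fails to bracket the point estimate (possible with few resamples) it is
reported as-is and flagged, not reordered.

## Known limitations

* **FOCE bias.**  With 15% proportional error and two samples per subject,
  FOCE+I carries an intrinsic O(sigma^2) bias (~+1.6% in theta_CL, ~1% in
  V1 and sigma_prop; the test-suite demonstrates by adaptive Gauss–Hermite
  profiling that the exact-likelihood optimum is unbiased while the FOCE
  optimum is not).  Covariate *coefficients* — the quantities this study is
  about — are unaffected (unbiased within Monte-Carlo error), but
  structural-parameter recovery at sub-percent precision and nominal Wald
  coverage at sigma = 0.15 are not achievable by this (or any faithful)
  FOCE implementation.
* The estimator is near Cramér–Rao efficient (its FOCE objective matches
  exact quadrature closely), so selection power here is the power of an
  essentially exact maximum-likelihood pipeline under the stated data
  model.  Production NONMEM/PsN pipelines on the same design can be less
  efficient (convergence failures count against selection), so absolute
  stepwise power values from such pipelines may run lower than this
  laboratory's at identical settings; the method *contrasts* (frem_posthoc
  vs scm ordering, collinearity and sample-size trends) are the robust
  quantities.
* The generator emulates a best-case covariate analysis: exactly one true
  covariate, Gaussian covariates, no time variation, no missingness, no
  inter-occasion variability, a correctly specified structural model.
  Passing tests show the engines' statistical behaviour under these
  conditions, not performance on messy clinical data.
* FREM with IIV on V1 links covariates to eta_CL only (eta_V independent) —
  sufficient for the categorical variant where coefficients are reported on
  CL, but not a general multi-parameter FREM.
* Single-pass SIR with an uninflated proposal (no iterative proposal
  updating); clinical-relevance filtering of effects is out of scope.
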