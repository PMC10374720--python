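# covselpk

**Operational characteristics of covariate-selection strategies in sparse
population pharmacokinetics, by simulation.**

When a population-PK modeller asks *"which patient covariates drive
clearance?"*, two automated strategies dominate practice:

* **SCM** (stepwise covariate modelling) — greedy forward inclusion of the
  covariate with the largest significant drop in objective function
  (likelihood-ratio test, χ²₁), followed by backward elimination at a
  stricter p-value;
* **FREM** (full random-effects modelling) — all covariates enter the model
  simultaneously *as observations*; a full covariance matrix Ω over
  (η_CL, η_cov₁…η_covK) encodes every covariate–parameter relationship, and
  the **univariate coefficient** of covariate *k*,

  ```
  coef_k = Ω[η_CL, η_cov_k] / Ω[η_cov_k, η_cov_k],
  ```

  is the implied effect of that covariate alone on log CL.  A posthoc
  selection step (**frem_posthoc**) retains covariates whose 90% confidence
  interval — from sampling importance resampling (SIR) — excludes zero.

`covselpk` is a self-contained laboratory for comparing these strategies on
their *operational characteristics*: statistical power to find the true
covariate, type-I error on a pure-noise covariate, conditional bias/precision
of the selected coefficient (selection bias!), and the fraction of
"predictive" models.  It bundles:

* a synthetic-data generator — three multivariate-normal covariates with
  configurable collinearity (0–90% between the true covariate and its
  companion), and sparse two-sample concentration data from a 1-compartment
  IV-infusion model (CL 18 L/h, V1 400 L, IIV on CL 0.1, 15% proportional
  error, 100 mg q12h over 30 min), exchanged as NONMEM-layout CSV;
* a **FOCE+I** nonlinear mixed-effects estimator (first-order conditional
  estimation with interaction), numba-accelerated, with retries, OFV in the
  NONMEM convention, and an inverse-Hessian estimate covariance;
* the SCM and FREM engines (FREM fitted through its exact full-fixed-effects
  marginalization, cross-checked against the joint covariates-as-observations
  likelihood), single-pass SIR, and the posthoc CI filter;
* the evaluation metrics and a scenario runner for the full factorial study
  (n ∈ {20, 50, 100, 500} × effect θ_cov ∈ {0.026, 0.032, 0.045} ×
  correlation ∈ {0 … 0.9} × scenario mode), with replicate-local seeding so
  parallel and serial runs are identical.

## Worked example

```bash
python examples/frem_with_sir.py
```

simulates 80 patients with a strong covariate effect (θ_cov = 0.045 on COVI,
50% correlated with COVII) and prints the fitted FREM:

```
SIR effective sample size: 509 of 1000
  COVI: coefficient +0.0516 CI90 (+0.0389, +0.0647) effect at q05/q95 -30.9%/+43.3% significant
  COVII: coefficient +0.0093 CI90 (+0.0052, +0.0134) effect at q05/q95 -20.6%/+23.7% significant
  COVIII: coefficient -0.0272 CI90 (-0.0667, +0.0157) effect at q05/q95 +6.3%/-7.9% n.s.

retained: ['COVI', 'COVII']; largest effect: COVI
```

COVI's coefficient (0.052) estimates the generating 0.045; COVII is
significant too because at 50% correlation it genuinely carries part of the
COVI information — exactly the collinearity behaviour the study quantifies —
while the noise covariate COVIII is not retained.  Other example scripts:
`simulate_and_fit.py` (simulator + FOCE+I base fit), `stepwise_selection.py`
(SCM decision trace), `power_study_cell.py` (one full study cell with power,
rbias, rrmse, type-I error).

A thin CLI wraps the same functions:

```bash
covselpk simulate --n 50 --theta-cov 0.026 --seed 1 --out ds.csv
covselpk scm ds.csv --forward-p 0.05 --backward-p 0.01
covselpk frem ds.csv
covselpk run-cell --n 50 --theta-cov 0.032 --replicates 100 --out cell.csv
covselpk run-study --config grid.yaml --out results/
```

## Notes

`docs/methods.md` documents the model, the FOCE+I objective, the FREM
marginalization, SIR, all default parameters, and the known limitations —
including the intrinsic O(σ²) FOCE bias that the test-suite quantifies
against an adaptive Gauss–Hermite oracle.
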