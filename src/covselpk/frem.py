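"""Full random-effects covariate modelling (FREM) with posthoc CI selection.

FREM treats the covariates as observations: each subject contributes, besides
the PK observations, one pseudo-observation per covariate modelled as
``cov_k = mu_k + eta_cov_k + eps_k`` with a tiny fixed residual, and a full
covariance matrix Omega over ``(eta_CL, eta_cov_1..K)`` captures the
covariate-parameter relationships.  The univariate covariate coefficient —
the implied effect of covariate ``k`` in isolation on log CL — is the ratio

    coef_k = Omega[eta_CL, eta_cov_k] / Omega[eta_cov_k, eta_cov_k].

Because the covariate block is linear-Gaussian, the joint likelihood can be
marginalized analytically: conditioning the eta_CL prior on the observed
covariates turns FREM into the mathematically equivalent full fixed-effects
model (all covariates on CL with coefficients ``b``, residual IIV ``v``),
multiplied by the closed-form multivariate-normal likelihood of the
covariates.  ``fit_frem`` exploits this: the covariate means/covariances are
profiled to their sample moments and the PK block is fitted by FOCE+I; the
agreement of this marginal formulation with the joint FOCE objective is part
of the test-suite contract (1e-6 relative OFV).

Uncertainty of the covariate coefficients comes from single-pass sampling
importance resampling (SIR) around the estimate covariance, and the
``frem_posthoc`` selection step retains covariates whose 90% SIR confidence
interval excludes zero, reporting the retained covariate with the largest
effect size (largest absolute fractional CL change at the covariate's 5th or
95th percentile).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import foce
from .foce import FitResult, ModelSpec
from .simulate import PKDataset

__all__ = [
    "FremModel",
    "UnivariateCoefficient",
    "FremSelection",
    "build_frem",
    "fit_frem",
    "joint_frem_ofv",
    "univariate_coefficient",
    "sir_ci",
    "sir_resample",
    "frem_posthoc",
]

log = logging.getLogger("covselpk")

#: pseudo-observation residual sd as a fraction of the covariate sd — fixed,
#: never estimated; makes covariate "observations" effectively exact
EPS_FRACTION = 1e-4


@dataclass(frozen=True)
class UnivariateCoefficient:
    """Implied effect of one covariate in isolation on log CL."""

    covariate: str
    value: float
    ci90: tuple | None = None
    #: fractional CL change at the covariate's empirical 5th/95th percentile
    effect_range: tuple | None = None
    ci_excludes_point: bool = False

    @property
    def significant(self) -> bool:
        if self.ci90 is None:
            return False
        lo, hi = self.ci90
        return lo > 0.0 or hi < 0.0

    @property
    def effect_size(self) -> float:
        """Ranking metric: larger absolute endpoint of the effect range."""
        if self.effect_range is None:
            return abs(self.value)
        return max(abs(self.effect_range[0]), abs(self.effect_range[1]))


@dataclass
class FremModel:
    """Fitted FREM: full covariance matrix plus marginal parameterization."""

    covariate_names: list
    theta_CL: float
    V1: float
    sigma_prop: float
    b: np.ndarray            # regression of eta_CL on centered covariates
    v: float                 # conditional (unexplained) IIV variance on CL
    mu: np.ndarray           # covariate means
    S: np.ndarray            # covariate covariance incl. pseudo-obs residual
    eps_sd: np.ndarray       # fixed tiny pseudo-observation residual sds
    fit: FitResult | None = None
    converged: bool = True

    @property
    def omega(self) -> np.ndarray:
        """(1+K)x(1+K) covariance over (eta_CL, eta_cov_1..K)."""
        K = len(self.covariate_names)
        om = np.empty((K + 1, K + 1))
        sigma = self.S - np.diag(self.eps_sd ** 2)
        c = self.S @ self.b
        om[0, 0] = self.v + float(self.b @ self.S @ self.b)
        om[0, 1:] = om[1:, 0] = c
        om[1:, 1:] = sigma
        return om

    def coefficient_value(self, k: int) -> float:
        c = self.S @ self.b
        return float(c[k] / self.omega[k + 1, k + 1])


def _covariate_moments(ds: PKDataset, names) -> tuple:
    X = ds.covariate_matrix(names)
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False, bias=True)  # ML (1/n) moments
    S = np.atleast_2d(S)
    return X, mu, S


def build_frem(covariate_names, ds: PKDataset, iiv_v: bool = False) -> ModelSpec:
    """The marginal (full fixed-effects) estimation model behind FREM.

    Each subject implicitly contributes ``K`` pseudo-observation rows; the
    marginal PK block is the model with every covariate on CL.  Raises on a
    constant covariate (its variability block would be singular).
    """
    X = ds.covariate_matrix(covariate_names)
    sds = X.std(axis=0)
    if np.any(sds <= 0):
        bad = [n for n, s in zip(covariate_names, sds) if s <= 0]
        raise ValueError(f"constant covariate(s) {bad}: zero variance")
    return ModelSpec(covariate_terms=tuple((n, "exp") for n in covariate_names),
                     iiv_v=iiv_v)


def fit_frem(ds: PKDataset, covariate_names=("COVI", "COVII", "COVIII"),
             seed=0, compute_cov: bool = True, iiv_v: bool = False) -> FremModel:
    """Maximum-likelihood FREM fit via the marginalized formulation.

    With ``iiv_v`` an additional independent random effect on V1 is
    estimated (the categorical-covariate study design); covariate
    coefficients remain reported on CL.
    """
    names = list(covariate_names)
    model = build_frem(names, ds, iiv_v=iiv_v)
    X, mu, S_lat = _covariate_moments(ds, names)
    eps_sd = EPS_FRACTION * np.sqrt(np.diag(S_lat))
    S = S_lat  # observed-scale covariance; latent = S - diag(eps^2)
    fit = foce.fit(model, ds, seed=seed, compute_cov=compute_cov,
                   centers={n: m for n, m in zip(names, mu)})
    if not fit.converged:
        log.warning("FREM marginal fit failed to converge")
        return FremModel(names, np.nan, np.nan, np.nan,
                         np.full(len(names), np.nan), np.nan, mu, S, eps_sd,
                         fit=fit, converged=False)
    est = fit.estimates
    b = np.array([est[f"beta_{n}"] for n in names])
    return FremModel(names, est["theta_CL"], est["V1"], est["sigma_prop"],
                     b, est["omega2_CL"], mu, S, eps_sd, fit=fit)


def joint_frem_ofv(m: FremModel, ds: PKDataset) -> float:
    """FREM OFV from the joint (unmarginalized) FOCE formulation.

    Builds the augmented observation vector (PK rows + one pseudo-observation
    per covariate) with the full (1+K)-dimensional eta and evaluates the
    general FOCE+I objective.  Serves as the cross-check that the fast
    marginal route computes the same likelihood.
    """
    from .pk import concentration

    names = m.covariate_names
    K = len(names)
    X = ds.covariate_matrix(names)
    times = np.asarray(ds.design.observation_times, dtype=float)
    J = times.size
    omega = m.omega
    sig2 = m.sigma_prop ** 2
    y_list, pred_fns, var_fns = [], [], []
    for i in range(ds.n_subjects):
        y_list.append(np.concatenate([ds.observations[i], X[i]]))

        def pred(eta, _i=i):
            cl = m.theta_CL * math.exp(eta[0])
            f_pk = concentration(cl, m.V1, ds.design, times)
            return np.concatenate([f_pk, m.mu + eta[1:]])

        def var(f, _i=i):
            return np.concatenate([sig2 * f[:J] ** 2, m.eps_sd ** 2])

        pred_fns.append(pred)
        var_fns.append(var)
    # warm-start: covariate etas are pinned near (x_i - mu) by the tiny
    # pseudo-observation residual; eta_CL near its conditional prior mean
    eta0_list = []
    Sinv_c = np.linalg.solve(m.S, m.S @ m.b)
    for i in range(ds.n_subjects):
        dev = X[i] - m.mu
        eta0_list.append(np.concatenate([[float(Sinv_c @ dev)], dev]))
    return foce.general_foce_ofv(y_list, pred_fns, var_fns, omega,
                                 eta0_list=eta0_list)


def marginal_frem_ofv(m: FremModel, ds: PKDataset) -> float:
    """FREM OFV as FFEM FOCE+I block + closed-form covariate MVN block."""
    names = m.covariate_names
    model = build_frem(names, ds)
    params = {"theta_CL": m.theta_CL, "V1": m.V1, "omega2_CL": m.v,
              "sigma_prop": m.sigma_prop}
    for n, bk in zip(names, m.b):
        params[f"beta_{n}"] = bk
    pk_ofv = foce.foce_objective(model, params, ds,
                                 centers={n: mu for n, mu in zip(names, m.mu)})
    return pk_ofv + _cov_block_neg2ll(ds.covariate_matrix(names), m.mu, m.S)


def _cov_block_neg2ll(X, mu, S) -> float:
    n, K = X.shape
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return np.inf
    dev = X - mu
    quad = float(np.sum(dev * np.linalg.solve(S, dev.T).T))
    # NONMEM-convention -2 log likelihood (2*pi constant omitted)
    return n * logdet + quad


def univariate_coefficient(m: FremModel, k, ds: PKDataset | None = None,
                           ci90=None) -> UnivariateCoefficient:
    """Coefficient for covariate ``k`` (index or name) with optional CI.

    ``effect_range`` uses the empirical 5th/95th covariate percentiles of
    ``ds`` (fractional change of CL relative to a subject at the mean).
    """
    if isinstance(k, str):
        k = m.covariate_names.index(k)
    name = m.covariate_names[k]
    if m.omega[k + 1, k + 1] <= 0:
        raise ValueError(f"covariate {name!r} has non-positive variance")
    value = m.coefficient_value(k)
    effect_range = None
    if ds is not None:
        x = ds.covariates[name].to_numpy(dtype=float)
        q05, q95 = np.quantile(x, [0.05, 0.95])
        effect_range = (math.exp(value * (q05 - m.mu[k])) - 1.0,
                        math.exp(value * (q95 - m.mu[k])) - 1.0)
    flag = False
    if ci90 is not None:
        lo, hi = ci90
        flag = not (lo <= value <= hi)
        if flag:
            log.warning("SIR 90%% CI for %s excludes the point estimate", name)
    return UnivariateCoefficient(covariate=name, value=value, ci90=ci90,
                                 effect_range=effect_range,
                                 ci_excludes_point=flag)


# ---------------------------------------------------------------------------
# sampling importance resampling
# ---------------------------------------------------------------------------

def sir_resample(ofv_fn, center, cov, n_samples, n_resamples, rng,
                 min_ess_fraction: float = 0.1):
    """Generic single-pass SIR.

    Draws ``n_samples`` parameter vectors from a multivariate-normal proposal
    ``N(center, cov)``, weights them by likelihood ratio
    ``exp(-(OFV - OFV_min)/2) / proposal_density`` and resamples
    ``n_resamples`` without replacement with probability proportional to the
    weights.  Returns ``(resampled_matrix, ess)``.
    """
    center = np.asarray(center, dtype=float)
    cov = np.asarray(cov, dtype=float)
    cov = (cov + cov.T) / 2.0
    w, Q = np.linalg.eigh(cov)
    w = np.maximum(w, 1e-12 * max(float(w.max()), 1e-12))
    cov = Q @ np.diag(w) @ Q.T
    samples = rng.multivariate_normal(center, cov, size=n_samples,
                                      method="cholesky")
    ofvs = np.array([ofv_fn(s) for s in samples])
    finite = np.isfinite(ofvs)
    log_q = stats.multivariate_normal.logpdf(samples, mean=center, cov=cov,
                                             allow_singular=True)
    log_w = np.where(finite, -(ofvs - np.nanmin(ofvs[finite])) / 2.0 - log_q,
                     -np.inf)
    log_w -= log_w[np.isfinite(log_w)].max()
    weights = np.exp(log_w)
    weights[~np.isfinite(weights)] = 0.0
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("all SIR weights vanished")
    p = weights / total
    ess = 1.0 / np.sum(p ** 2)
    if ess < min_ess_fraction * n_samples:
        log.warning("SIR effective sample size low: %.1f of %d", ess, n_samples)
    n_take = min(n_resamples, int(np.sum(p > 0)))
    idx = rng.choice(n_samples, size=n_take, replace=False, p=p)
    return samples[idx], float(ess)


def _chol_params(S_lat: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(S_lat)
    K = L.shape[0]
    out = []
    for i in range(K):
        for j in range(i + 1):
            out.append(math.log(L[i, i]) if i == j else L[i, j])
    return np.asarray(out)


def _chol_expand(vec: np.ndarray, K: int) -> np.ndarray:
    L = np.zeros((K, K))
    t = 0
    for i in range(K):
        for j in range(i + 1):
            L[i, j] = math.exp(vec[t]) if i == j else vec[t]
            t += 1
    return L


def sir_ci(m: FremModel, ds: PKDataset, n_samples: int = 1000,
           n_resamples: int = 500, seed=0, level: float = 0.90):
    """SIR confidence intervals of every univariate covariate coefficient.

    The sampled parameter vector spans the full FREM parameterization —
    the PK block (theta_CL, V1, covariate regression coefficients, residual
    IIV, proportional error) and the covariate block (means and the Cholesky
    factor of the covariate covariance) — so coefficient uncertainty includes
    both sources.  Returns ``{name: (low, high)}`` plus the resampled
    coefficient draws, as ``(cis, draws, ess)``.
    """
    if m.fit is None or m.fit.cov_x is None:
        raise ValueError("fit with compute_cov=True is required for SIR")
    names = m.covariate_names
    K = len(names)
    X = ds.covariate_matrix(names)
    n = X.shape[0]
    eps2 = m.eps_sd ** 2
    S_lat = m.S - np.diag(eps2)
    x_pk = m.fit.x_opt
    p_pk = x_pk.size
    x_cov = np.concatenate([m.mu, _chol_params(S_lat)])

    problem = foce.FoceProblem(m.fit.model, ds,
                               centers={nm: mu for nm, mu in zip(names, m.mu)})

    def cov_ofv(xc):
        mu = xc[:K]
        L = _chol_expand(xc[K:], K)
        S = L @ L.T + np.diag(eps2)
        return _cov_block_neg2ll(X, mu, S)

    H_cov = foce._numeric_hessian(cov_ofv, x_cov, rel_step=1e-4)
    try:
        cov_cov = 2.0 * np.linalg.inv(H_cov)
    except np.linalg.LinAlgError:
        cov_cov = np.diag(np.full(x_cov.size, 1e-6))
    cov_full = np.zeros((p_pk + x_cov.size, p_pk + x_cov.size))
    cov_full[:p_pk, :p_pk] = m.fit.cov_x
    cov_full[p_pk:, p_pk:] = cov_cov
    center = np.concatenate([x_pk, x_cov])

    beta_idx = [m.fit.param_names.index(f"beta_{nm}") for nm in names]

    def total_ofv(phi):
        pk = problem.ofv_x(phi[:p_pk])
        if not np.isfinite(pk):
            return np.inf
        return pk + cov_ofv(phi[p_pk:])

    rng = np.random.default_rng(seed)
    resampled, ess = sir_resample(total_ofv, center, cov_full,
                                  n_samples, n_resamples, rng)

    def coefs(phi):
        b = phi[beta_idx]
        mu = phi[p_pk:p_pk + K]
        L = _chol_expand(phi[p_pk + K:], K)
        S = L @ L.T + np.diag(eps2)
        c = S @ b
        return c / np.diag(L @ L.T)

    draws = np.array([coefs(phi) for phi in resampled])
    alpha = (1.0 - level) / 2.0
    cis = {}
    for k, nm in enumerate(names):
        lo, hi = np.quantile(draws[:, k], [alpha, 1.0 - alpha])
        cis[nm] = (float(lo), float(hi))
    return cis, draws, ess


@dataclass
class FremSelection:
    """Outcome of the posthoc CI-based backward elimination."""

    coefficients: list            # UnivariateCoefficient, one per covariate
    retained: list                # names with 90% CI excluding zero
    largest_effect: str | None    # retained covariate with largest effect size

    def power_event(self, true_covariate: str) -> bool:
        """True covariate retained with the largest effect size."""
        return (true_covariate in self.retained
                and self.largest_effect == true_covariate)


def frem_posthoc(m: FremModel, cis, ds: PKDataset | None = None) -> FremSelection:
    """Retain covariates whose 90% CI excludes zero; rank by effect size."""
    coefficients = [univariate_coefficient(m, k, ds=ds, ci90=cis[nm])
                    for k, nm in enumerate(m.covariate_names)]
    retained = [c.covariate for c in coefficients if c.significant]
    largest = None
    if retained:
        sig = [c for c in coefficients if c.significant]
        largest = max(sig, key=lambda c: c.effect_size).covariate
    return FremSelection(coefficients=coefficients, retained=retained,
                         largest_effect=largest)
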