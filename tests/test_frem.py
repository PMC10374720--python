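import math

import numpy as np
import pytest

from covselpk import foce, frem
from covselpk import simulate as sim


def _dataset(n=12, theta=0.03, corr=0.4, seed=600):
    covs = sim.sample_covariates(sim.default_covariate_specs(), corr, n, seed=seed)
    return sim.simulate_dataset(covs, sim.default_design(),
                                sim.default_true_params(theta), seed=seed + 1)


def _random_frem_model(ds, rng):
    names = ["COVI", "COVII", "COVIII"]
    X = ds.covariate_matrix(names)
    S_lat = np.cov(X, rowvar=False, bias=True)
    eps_sd = frem.EPS_FRACTION * np.sqrt(np.diag(S_lat))
    return frem.FremModel(
        covariate_names=names,
        theta_CL=rng.uniform(15, 21), V1=rng.uniform(350, 450),
        sigma_prop=rng.uniform(0.1, 0.2),
        b=rng.normal(0, 0.01, 3), v=rng.uniform(0.05, 0.15),
        mu=X.mean(axis=0), S=S_lat + np.diag(eps_sd ** 2), eps_sd=eps_sd)


class TestBuildFrem:
    def test_constant_covariate_rejected(self):
        ds = _dataset(n=8)
        ds.covariates["COVIII"] = 5.0
        with pytest.raises(ValueError, match="COVIII"):
            frem.build_frem(["COVI", "COVII", "COVIII"], ds)

    def test_model_has_all_covariates_on_cl(self):
        ds = _dataset(n=8)
        model = frem.build_frem(["COVI", "COVII", "COVIII"], ds)
        assert [c for c, _ in model.covariate_terms] == ["COVI", "COVII", "COVIII"]


class TestLikelihoodEquivalence:
    def test_marginal_matches_joint_foce(self):
        # the analytically marginalized covariate block must reproduce the
        # joint (covariates-as-observations) FOCE objective: 1e-6 relative
        rng = np.random.default_rng(61)
        for k in range(10):
            ds = _dataset(n=8, theta=rng.uniform(0, 0.05),
                          corr=rng.uniform(0, 0.8), seed=700 + k)
            m = _random_frem_model(ds, rng)
            joint = frem.joint_frem_ofv(m, ds)
            marginal = frem.marginal_frem_ofv(m, ds)
            assert abs(joint - marginal) / abs(joint) < 1e-6

    def test_zero_cross_covariance_separates_blocks(self):
        # b = 0: the FREM OFV is exactly base-model OFV + covariate MVN block
        ds = _dataset(n=20)
        m = _random_frem_model(ds, np.random.default_rng(3))
        m.b = np.zeros(3)
        params = {"theta_CL": m.theta_CL, "V1": m.V1, "omega2_CL": m.v,
                  "sigma_prop": m.sigma_prop}
        base = foce.foce_objective(foce.ModelSpec(), params, ds)
        assert frem.marginal_frem_ofv(m, ds) == pytest.approx(
            base + frem._cov_block_neg2ll(ds.covariate_matrix(m.covariate_names),
                                          m.mu, m.S), rel=1e-12)

    def test_profiled_covariate_moments_are_the_mle(self):
        # sample mean / ML covariance minimize the covariate block
        ds = _dataset(n=30)
        X = ds.covariate_matrix(["COVI", "COVII", "COVIII"])
        mu = X.mean(axis=0)
        S = np.cov(X, rowvar=False, bias=True)
        best = frem._cov_block_neg2ll(X, mu, S)
        rng = np.random.default_rng(4)
        for _ in range(20):
            dmu = mu + rng.normal(0, 0.3, 3)
            dS = S * rng.uniform(0.8, 1.2)
            assert frem._cov_block_neg2ll(X, dmu, dS) > best


class TestUnivariateCoefficient:
    def test_hand_computed_ratio(self):
        ds = _dataset(n=10)
        m = _random_frem_model(ds, np.random.default_rng(5))
        # force Omega[CL,k] = 0.12 and Omega[k,k] = 21.6 for COVI
        m.S = np.diag([21.6, 225.0, 4.0])
        m.eps_sd = np.zeros(3)
        m.b = np.linalg.solve(m.S, np.array([0.12, 0.0, 0.0]))
        c = frem.univariate_coefficient(m, 0)
        assert c.value == pytest.approx(0.12 / 21.6, rel=1e-10)
        assert c.value == pytest.approx(0.005556, abs=5e-7)

    def test_zero_covariance_gives_zero_effect(self):
        ds = _dataset(n=10)
        m = _random_frem_model(ds, np.random.default_rng(6))
        m.b = np.zeros(3)
        c = frem.univariate_coefficient(m, 1, ds=ds)
        assert c.value == 0.0
        assert c.effect_range == (0.0, 0.0)

    def test_rescaling_covariate_rescales_coefficient(self):
        # x -> c*x: coefficient scales by 1/c, effect range is unchanged
        ds = _dataset(n=60, theta=0.04, seed=800)
        m1 = frem.fit_frem(ds, seed=1, compute_cov=False)
        ds2 = sim.PKDataset(covariates=ds.covariates.assign(COVI=ds.covariates.COVI * 2),
                            observations=ds.observations, design=ds.design)
        m2 = frem.fit_frem(ds2, seed=1, compute_cov=False)
        c1 = frem.univariate_coefficient(m1, 0, ds=ds)
        c2 = frem.univariate_coefficient(m2, 0, ds=ds2)
        assert c2.value == pytest.approx(c1.value / 2.0, rel=0.02)
        assert c2.effect_range[1] == pytest.approx(c1.effect_range[1], rel=0.03)

    def test_coefficient_recovers_generating_effect(self):
        ds = _dataset(n=400, theta=0.045, corr=0.5, seed=900)
        m = frem.fit_frem(ds, seed=1, compute_cov=False)
        assert m.coefficient_value(0) == pytest.approx(0.045, abs=0.012)


class TestSir:
    def test_uniform_weights_resample_proposal(self):
        # likelihood proportional to the proposal: importance weights are
        # constant, ESS ~ n and the resample reproduces proposal percentiles
        rng = np.random.default_rng(7)
        samples, ess = frem.sir_resample(lambda x: float(x @ x), np.zeros(1),
                                         np.eye(1), 4000, 2000, rng)
        lo, hi = np.quantile(samples[:, 0], [0.05, 0.95])
        assert lo == pytest.approx(-1.645, abs=0.15)
        assert hi == pytest.approx(1.645, abs=0.15)
        assert ess > 3800

    def test_seed_reproducibility(self):
        ds = _dataset(n=25, theta=0.045, seed=820)
        m = frem.fit_frem(ds, seed=1)
        a = frem.sir_ci(m, ds, n_samples=300, n_resamples=150, seed=42)[0]
        b = frem.sir_ci(m, ds, n_samples=300, n_resamples=150, seed=42)[0]
        assert a == b

    def test_gaussian_target_matches_wald(self):
        # quadratic OFV: SIR percentiles equal the normal-theory interval
        rng = np.random.default_rng(8)
        A = np.diag([4.0, 1.0])

        def ofv(x):
            return float(x @ A @ x)

        cov = 2.0 * np.linalg.inv(2.0 * A)  # 2 H^{-1} with H = 2A
        samples, _ = frem.sir_resample(ofv, np.zeros(2), cov, 4000, 2000, rng)
        sd0 = math.sqrt(cov[0, 0])
        lo, hi = np.quantile(samples[:, 0], [0.05, 0.95])
        assert lo == pytest.approx(-1.645 * sd0, abs=0.12 * sd0)
        assert hi == pytest.approx(1.645 * sd0, abs=0.12 * sd0)


class TestPosthoc:
    def _model(self):
        ds = _dataset(n=10)
        return _random_frem_model(ds, np.random.default_rng(9)), ds

    def test_all_straddling_cis_retain_nothing(self):
        m, ds = self._model()
        cis = {n: (-0.01, 0.02) for n in m.covariate_names}
        sel = frem.frem_posthoc(m, cis, ds=ds)
        assert sel.retained == []
        assert sel.largest_effect is None
        assert not sel.power_event("COVI")

    def test_only_true_covariate_significant(self):
        m, ds = self._model()
        m.b = np.array([0.03, 0.0, 0.0])
        cis = {"COVI": (0.01, 0.05), "COVII": (-0.01, 0.01),
               "COVIII": (-0.02, 0.02)}
        sel = frem.frem_posthoc(m, cis, ds=ds)
        assert sel.retained == ["COVI"]
        assert sel.power_event("COVI")

    def test_larger_competing_effect_defeats_power_event(self):
        m, ds = self._model()
        # both significant; COVII's implied effect range is larger
        m.S = np.diag([21.6, 225.0, 4.0]) + np.diag(m.eps_sd ** 2)
        m.b = np.linalg.solve(m.S, np.array([0.05, 0.9, 0.0]))
        cis = {"COVI": (0.001, 0.004), "COVII": (0.002, 0.006),
               "COVIII": (-0.02, 0.02)}
        sel = frem.frem_posthoc(m, cis, ds=ds)
        assert "COVI" in sel.retained and "COVII" in sel.retained
        assert sel.largest_effect == "COVII"
        assert not sel.power_event("COVI")


class TestSelectionBiasContrast:
    def test_unselected_frem_coefficients_unbiased_scm_conditional_biased(self):
        # the quantitative signature of selection bias: over replicates at
        # n=50, all frem coefficients center on the truth while the mean of
        # scm coefficients conditional on selection sits above it
        from covselpk import scm as scm_mod

        theta = 0.026
        frem_coefs, scm_coefs = [], []
        for r in range(100):
            covs = sim.sample_covariates(sim.default_covariate_specs(), 0.0,
                                         50, seed=4000 + r)
            ds = sim.simulate_dataset(covs, sim.default_design(),
                                      sim.default_true_params(theta),
                                      seed=5000 + r)
            m = frem.fit_frem(ds, seed=r, compute_cov=False)
            if m.converged:
                frem_coefs.append(m.coefficient_value(0))
            res = scm_mod.run_scm(ds, scm_mod.ScmSettings(), seed=r)
            if res.contains("COVI"):
                scm_coefs.append(res.coefficient("COVI"))
        frem_coefs = np.array(frem_coefs)
        mc_se = frem_coefs.std(ddof=1) / math.sqrt(len(frem_coefs))
        assert abs(frem_coefs.mean() - theta) < 3 * mc_se
        assert np.mean(scm_coefs) > theta + 2 * mc_se
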