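"""Independent oracles used by the test-suite.

Everything here is deliberately coded independently of the package's
implementation paths: the marginal likelihood by adaptive Gauss-Hermite
quadrature, the concentration profile by stiff ODE integration of the dosing
system, and concentration moments by deterministic quadrature over the
log-normal clearance distribution.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar


def ode_concentration(CL, V, design, times):
    """1-compartment infusion profile via numerical ODE integration.

    dA/dt = rate(t) - (CL/V) A, integrated piecewise over infusion on/off
    segments so the discontinuous input is handled exactly.
    """
    k = CL / V
    r0 = design.dose_amount / design.infusion_duration
    boundaries = []
    for d in range(design.n_doses):
        t0 = d * design.dosing_interval
        boundaries.append((t0, t0 + design.infusion_duration))
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    for idx, t_end in enumerate(times):
        seg_pts = sorted({0.0, t_end}
                         | {b for se in boundaries for b in se if b < t_end})
        amount = 0.0
        for a, b in zip(seg_pts[:-1], seg_pts[1:]):
            infusing = any(s <= a < e for s, e in boundaries)
            rate = r0 if infusing else 0.0
            sol = solve_ivp(lambda t, y: rate - k * y[0], (a, b), [amount],
                            method="LSODA", rtol=1e-10, atol=1e-12)
            amount = float(sol.y[0, -1])
        out[idx] = amount / V
    return out


def agq_ofv(params, ds, covariate_terms=(), centers=None, n_nodes=64):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Scalar random effect on CL; exponential/fractional covariate terms on CL
    as in the estimation model.  Comparable to the package FOCE OFV
    (NONMEM convention: the n_obs*log(2*pi) constant is omitted).
    """
    from covselpk.pk import concentration

    z, w = hermegauss(n_nodes)
    times = np.asarray(ds.design.observation_times, dtype=float)
    om2 = params["omega2_CL"]
    sig = params["sigma_prop"]
    total = 0.0
    for i in range(ds.n_subjects):
        y = ds.observations[i]
        log_cl = math.log(params["theta_CL"])
        for name, form in covariate_terms:
            x = float(ds.covariates[name].iloc[i])
            beta = params[f"beta_{name}"]
            if form == "exp":
                log_cl += beta * (x - centers[name])
            else:
                log_cl += math.log(1.0 + beta * x)

        def neg2_joint(eta):
            cl = math.exp(log_cl + eta)
            f = concentration(cl, params["V1"], ds.design, times)
            v = (sig * f) ** 2
            return float(np.sum((y - f) ** 2 / v + np.log(2 * np.pi * v))
                         + eta * eta / om2 + math.log(2 * np.pi * om2))

        res = minimize_scalar(neg2_joint, bounds=(-6, 6), method="bounded",
                              options={"xatol": 1e-12})
        mode = res.x
        h = 1e-4
        curv = (neg2_joint(mode + h) - 2 * neg2_joint(mode)
                + neg2_joint(mode - h)) / h ** 2
        s = math.sqrt(2.0 / max(curv, 1e-8))
        nodes = mode + s * z
        log_terms = np.array([-0.5 * neg2_joint(t) for t in nodes])
        log_terms += 0.5 * z ** 2 + np.log(w) + math.log(s)
        m = log_terms.max()
        total += -2.0 * (m + math.log(np.sum(np.exp(log_terms - m))))
        total -= y.size * math.log(2.0 * math.pi)
    return total


def concentration_moments(theta_CL, V1, design, times, log_cl_var, sigma_prop,
                          n_nodes=128):
    """Mean and variance of observed concentrations by quadrature.

    Integrates over the combined log-normal clearance distribution
    (IIV plus any exponential covariate contribution folded into
    ``log_cl_var``) and applies the proportional-error moments exactly.
    """
    from covselpk.pk import concentration

    z, w = hermegauss(n_nodes)
    w = w / w.sum()
    times = np.asarray(times, dtype=float)
    sd = math.sqrt(log_cl_var)
    c = np.array([concentration(theta_CL * math.exp(sd * zi), V1, design, times)
                  for zi in z])
    mean_c = w @ c
    mean_c2 = w @ (c ** 2)
    mean_obs = mean_c                      # E[1 + eps] = 1
    var_obs = mean_c2 * (1.0 + sigma_prop ** 2) - mean_c ** 2
    return mean_obs, var_obs
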