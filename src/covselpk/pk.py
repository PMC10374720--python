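"""Analytic one-compartment IV-infusion model with covariate effects on clearance.

The structural model is the classic intermittent-infusion superposition
solution.  For a dose delivered at rate ``R0`` over ``T_inf`` hours starting at
time ``t_d``, with elimination rate constant ``k = CL/V``, the contribution to
the concentration at ``t >= t_d`` (``tau = t - t_d``) is

    during the infusion:   (R0/CL) * (1 - exp(-k*tau))
    after the infusion:    (R0/CL) * (1 - exp(-k*T_inf)) * exp(-k*(tau - T_inf))

and doses superpose linearly.  Individual clearance follows a log-normal
inter-individual model with exponential (continuous) or fractional
(dichotomous) covariate terms:

    CL_i = theta_CL * prod_k m_k(cov_ik) * exp(eta_i)

with ``m_k = exp(theta_k * (cov - center))`` for continuous covariates and
``m_k = 1 + theta_k * cov`` (cov in {0, 1}) for dichotomous ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "StructuralParams",
    "individual_CL",
    "concentration",
    "concentration_grad",
    "predict_dataset",
]


@dataclass
class StructuralParams:
    """True (or estimated) parameters of the structural + stochastic model.

    Units: ``theta_CL`` L/h, ``V1`` L, variances on the log scale,
    ``sigma_prop`` as a fraction (0.15 = 15% CV).
    """

    theta_CL: float = 18.0
    V1: float = 400.0
    omega2_CL: float = 0.1
    omega2_V: float = 0.0
    sigma_prop: float = 0.15
    #: covariate name -> coefficient (per unit for continuous, fractional
    #: change of CL for category 1 of a dichotomous covariate)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    #: covariate name -> centering value (continuous covariates only)
    covariate_centers: Mapping[str, float] = field(default_factory=dict)
    #: names of covariates whose effect is fractional (dichotomous)
    fractional: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.theta_CL <= 0 or self.V1 <= 0:
            raise ValueError("theta_CL and V1 must be positive")
        if self.omega2_CL < 0 or self.omega2_V < 0 or self.sigma_prop < 0:
            raise ValueError("variance parameters must be non-negative")


def individual_CL(params: StructuralParams, covariates: Mapping[str, float],
                  eta: float) -> float:
    """Individual clearance for one subject.

    ``covariates`` must contain every name in ``params.covariate_effects``.
    Raises ``ValueError`` if a fractional effect drives CL to zero or below.
    """
    log_cl = math.log(params.theta_CL)
    for name, coef in params.covariate_effects.items():
        value = covariates[name]
        if name in params.fractional:
            mult = 1.0 + coef * value
            if mult <= 0.0:
                raise ValueError(
                    f"fractional covariate effect on {name!r} makes CL non-positive")
            log_cl += math.log(mult)
        else:
            center = params.covariate_centers.get(name, 0.0)
            log_cl += coef * (value - center)
    return math.exp(log_cl + eta)


def concentration(CL: float, V: float, design, t) -> np.ndarray | float:
    """Concentration (mg/L) at time(s) ``t`` under the repeated-infusion design.

    Exact superposition solution; no ODE solver.  ``design`` is a
    :class:`covselpk.simulate.DesignSpec`.
    """
    if CL <= 0 or V <= 0:
        raise ValueError("CL and V must be positive (k = CL/V > 0)")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    k = CL / V
    r0 = design.dose_amount / design.infusion_duration
    c = np.zeros_like(t_arr)
    for d in range(design.n_doses):
        tau = t_arr - d * design.dosing_interval
        active = tau > 0
        if not active.any():
            continue
        ta = np.minimum(tau[active], design.infusion_duration)
        tb = np.maximum(tau[active] - design.infusion_duration, 0.0)
        c[active] += (r0 / CL) * (1.0 - np.exp(-k * ta)) * np.exp(-k * tb)
    return c if np.ndim(t) else float(c[0])


def concentration_grad(CL: float, V: float, design, t):
    """Concentration and its partial derivatives w.r.t. CL and V.

    Returns ``(c, dc_dCL, dc_dV)`` as arrays over ``t``.  Used by the FOCE
    linearization; derivatives are analytic.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    k = CL / V
    r0 = design.dose_amount / design.infusion_duration
    c = np.zeros_like(t_arr)
    dc_dk = np.zeros_like(t_arr)
    for d in range(design.n_doses):
        tau = t_arr - d * design.dosing_interval
        active = tau > 0
        if not active.any():
            continue
        ta = np.minimum(tau[active], design.infusion_duration)
        tb = np.maximum(tau[active] - design.infusion_duration, 0.0)
        e1 = np.exp(-k * ta)
        e2 = np.exp(-k * tb)
        c[active] += (r0 / CL) * (1.0 - e1) * e2
        dc_dk[active] += (r0 / CL) * (ta * e1 * e2 - tb * (1.0 - e1) * e2)
    dc_dCL = -c / CL + dc_dk / V
    dc_dV = -dc_dk * k / V
    return c, dc_dCL, dc_dV


def predict_dataset(params: StructuralParams, ds, etas) -> np.ndarray:
    """Noise-free predicted concentrations for every observation in ``ds``.

    ``etas`` is ``(n,)`` (eta on CL) or ``(n, 2)`` (eta on CL and V) with one
    row per subject in dataset order; returns an ``(n, n_obs)`` array.
    """
    etas = np.asarray(etas, dtype=float)
    if etas.ndim == 1:
        etas = np.column_stack([etas, np.zeros_like(etas)])
    n = ds.n_subjects
    if etas.shape[0] != n:
        raise ValueError(f"expected {n} eta rows, got {etas.shape[0]}")
    times = np.asarray(ds.design.observation_times, dtype=float)
    out = np.empty((n, times.size))
    for i in range(n):
        cov_i = {name: ds.covariates[name].iloc[i] for name in ds.covariates.columns}
        cl_i = individual_CL(params, cov_i, etas[i, 0])
        v_i = params.V1 * math.exp(etas[i, 1])
        out[i] = concentration(cl_i, v_i, ds.design, times)
    return out
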