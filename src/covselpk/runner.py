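"""Orchestration of the simulation study: scenario cells, replicates, seeds.

One scenario cell is a (n_subjects, theta_cov, correlation, scenario mode)
combination; a cell run simulates ``replicates`` datasets and runs both
covariate-selection engines on each identical dataset (paired comparison),
then reduces the outcomes to the study metrics.  Seeding is replicate-local
(``base_seed + replicate``) with independent substreams for covariate,
residual, fit-retry and SIR randomness, so results are independent of
execution order and worker count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import frem as frem_mod
from . import scm as scm_mod
from . import simulate as sim
from .metrics import ReplicateOutcome, metrics_table
from .scm import ScmSettings

__all__ = ["ScenarioConfig", "run_replicate", "run_cell", "run_study"]

log = logging.getLogger("covselpk")


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation-study grid."""

    n_subjects: int = 50
    theta_cov: float = 0.026
    corr: float = 0.0
    replicates: int = 1000
    scenario_mode: int = 1      # 1: scm 0.05/0.01; 2: scm 0.1/forward-only
    base_seed: int = 12345
    sir_samples: int = 1000
    sir_resamples: int = 500
    ci_level: float = 0.90
    categorical: bool = False   # dichotomous true covariate, IIV also on V1
    frac_effect: float = -0.2   # fractional CL change (categorical variant)
    omega2_V: float = 0.1       # IIV on V1 (categorical variant)

    def __post_init__(self) -> None:
        if self.scenario_mode not in (1, 2, 3):
            raise ValueError("scenario_mode must be 1, 2 or 3")

    @property
    def scm_settings(self) -> ScmSettings:
        if self.categorical:
            cands = (("COVI", "frac"), ("COVII", "exp"), ("COVIII", "exp"))
        else:
            cands = (("COVI", "exp"), ("COVII", "exp"), ("COVIII", "exp"))
        if self.scenario_mode == 2:
            return ScmSettings(forward_p=0.1, backward_p=None, candidates=cands,
                               iiv_v=self.categorical)
        return ScmSettings(forward_p=0.05, backward_p=0.01, candidates=cands,
                           iiv_v=self.categorical)

    @property
    def true_coefficient(self) -> float:
        return self.frac_effect if self.categorical else self.theta_cov

    def covariate_specs(self):
        specs = sim.default_covariate_specs()
        if self.categorical:
            specs[0] = sim.CovariateSpec("COVI", kind="dichotomous",
                                         prevalence=0.5, role="true-covariate")
        return specs

    def true_params(self):
        if self.categorical:
            return sim.default_true_params(self.frac_effect, fractional=True,
                                           omega2_V=self.omega2_V)
        return sim.default_true_params(self.theta_cov)


def simulate_replicate(cfg: ScenarioConfig, replicate: int) -> sim.PKDataset:
    """The dataset both engines see for this replicate."""
    ss = np.random.SeedSequence(cfg.base_seed + replicate)
    cov_seed, sim_seed, _, _ = ss.spawn(4)
    covs = sim.sample_covariates(cfg.covariate_specs(), cfg.corr,
                                 cfg.n_subjects, cov_seed)
    return sim.simulate_dataset(covs, sim.default_design(), cfg.true_params(),
                                sim_seed)


def run_replicate(cfg: ScenarioConfig, replicate: int,
                  engines=("scm", "frem")) -> list:
    """Simulate one dataset and run the engines; returns ReplicateOutcomes."""
    ss = np.random.SeedSequence(cfg.base_seed + replicate)
    _, _, fit_seed, sir_seed = ss.spawn(4)
    ds = simulate_replicate(cfg, replicate)
    outcomes = []

    if "scm" in engines:
        scm_res = scm_mod.run_scm(ds, cfg.scm_settings, seed=fit_seed)
        scm_ok = scm_res.base_converged and scm_res.final_fit is not None \
            and scm_res.final_fit.converged
        outcomes.append(ReplicateOutcome(
            replicate=replicate, method="scm", converged=scm_ok,
            selected_true=scm_ok and scm_res.contains("COVI"),
            estimated_coefficient=scm_res.coefficient("COVI") if scm_ok else None,
            noise_selected=scm_ok and scm_res.forward_contains("COVIII"),
            covII_selected=scm_ok and scm_res.contains("COVII")))
    if "frem" not in engines:
        return outcomes

    m = frem_mod.fit_frem(ds, seed=fit_seed, iiv_v=cfg.categorical)
    if m.converged and m.fit.cov_x is not None:
        cis, _, _ = frem_mod.sir_ci(m, ds, n_samples=cfg.sir_samples,
                                    n_resamples=cfg.sir_resamples,
                                    seed=sir_seed, level=cfg.ci_level)
        sel = frem_mod.frem_posthoc(m, cis, ds=ds)
        coef = m.coefficient_value(0)
        outcomes.append(ReplicateOutcome(
            replicate=replicate, method="frem_posthoc", converged=True,
            selected_true=sel.power_event("COVI"),
            estimated_coefficient=coef if sel.power_event("COVI") else None,
            noise_selected="COVIII" in sel.retained,
            covII_selected="COVII" in sel.retained))
        outcomes.append(ReplicateOutcome(
            replicate=replicate, method="frem_all", converged=True,
            estimated_coefficient=coef))
    else:
        outcomes.append(ReplicateOutcome(replicate=replicate,
                                         method="frem_posthoc", converged=False))
        outcomes.append(ReplicateOutcome(replicate=replicate,
                                         method="frem_all", converged=False))
    return outcomes


def run_cell(cfg: ScenarioConfig, n_jobs: int = 1):
    """Run every replicate of one cell; returns (metrics frame, outcomes)."""
    if n_jobs == 1:
        blocks = [run_replicate(cfg, r) for r in range(cfg.replicates)]
    else:
        blocks = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(cfg, r) for r in range(cfg.replicates))
    outcomes = [o for block in blocks for o in block]
    n_conv = sum(o.converged for o in outcomes if o.method == "scm")
    if n_conv == 0:
        raise RuntimeError(f"cell {cfg}: no converged replicates")
    table = metrics_table(outcomes, cfg.true_coefficient, cfg.n_subjects,
                          cfg.corr, cfg.theta_cov)
    return table, outcomes


def run_study(config, out_dir=None, n_jobs: int = 1) -> pd.DataFrame:
    """Run a grid of cells from a YAML file or an in-memory mapping.

    The config maps ``defaults`` (any ScenarioConfig field) and ``cells``
    (list of per-cell overrides).  Returns the concatenated tidy metrics
    table, and writes ``metrics.csv`` plus a JSON run manifest when
    ``out_dir`` is given.
    """
    if isinstance(config, (str, bytes)) or hasattr(config, "read"):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    defaults = config.get("defaults", {})
    cells = config.get("cells", [])
    tables = []
    failures = []
    for spec in cells:
        cfg = ScenarioConfig(**{**defaults, **spec})
        try:
            table, _ = run_cell(cfg, n_jobs=n_jobs)
            tables.append(table)
        except Exception as exc:  # pragma: no cover - partial-failure path
            log.error("cell %s failed: %s", spec, exc)
            failures.append({"cell": spec, "error": str(exc)})
    result = (pd.concat(tables, ignore_index=True) if tables
              else pd.DataFrame(columns=["method", "n", "corr", "theta_cov",
                                         "metric", "value", "n_used"]))
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "metrics.csv", index=False)
        manifest = {"defaults": defaults, "cells": cells,
                    "n_cells_ok": len(tables), "failures": failures}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if failures:
        raise RuntimeError(f"{len(failures)} cell(s) failed; see log")
    return result
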