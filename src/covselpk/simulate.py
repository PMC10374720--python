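"""Synthetic study data: correlated covariates and sparse PK observations.

Generates the replicate datasets of the simulation study: three covariates per
subject drawn from a multivariate normal (the true covariate, a companion
correlated with it at 0-90%, and an independent noise covariate), and two
sparse concentration samples per subject from a 1-compartment IV-infusion
model (100 mg q12h over 30 min; samples in the sixth and twelfth dosing
interval).  Datasets round-trip through NONMEM-layout CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pk import StructuralParams, predict_dataset

__all__ = [
    "CovariateSpec",
    "DesignSpec",
    "PKDataset",
    "default_covariate_specs",
    "default_design",
    "default_true_params",
    "sample_covariates",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

#: spread of the true covariate chosen so that a coefficient of 0.026 gives a
#: +22% clearance effect at the 95th percentile: sd = ln(1.22)/(0.026 * z_95)
COV_TRUE_SD = float(np.log(1.22) / (0.026 * stats.norm.ppf(0.95)))


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate of the study population.

    ``role`` is one of ``"true-covariate"`` (drives clearance),
    ``"correlated"`` (companion, correlated with the true covariate) or
    ``"noise"`` (independent dummy).  Dichotomous covariates are produced by
    thresholding a latent normal coordinate at the quantile matching
    ``prevalence``; the configured correlation lives on the latent scale.
    """

    name: str
    kind: str = "continuous"  # continuous | dichotomous
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5
    role: str = "noise"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "dichotomous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "continuous" and self.sd <= 0:
            raise ValueError("continuous covariate needs sd > 0")
        if self.kind == "dichotomous" and not 0.0 < self.prevalence < 1.0:
            raise ValueError("dichotomous prevalence must be in (0, 1)")


@dataclass(frozen=True)
class DesignSpec:
    """Common dosing and sampling design shared by every subject."""

    dose_amount: float = 100.0          # mg
    infusion_duration: float = 0.5      # h
    dosing_interval: float = 12.0       # h
    n_doses: int = 12
    #: h after the first dose start; defaults are 1 h after the 6th dose and
    #: 11.5 h after the 12th dose (the sparse two-sample design)
    observation_times: tuple = (61.0, 143.5)

    def __post_init__(self) -> None:
        times = np.asarray(self.observation_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise ValueError("observation_times must be strictly increasing")
        if np.any(times <= 0):
            raise ValueError("observations at t <= 0 are rejected (zero "
                             "prediction makes proportional error undefined)")
        if not 0 < self.infusion_duration < self.dosing_interval:
            raise ValueError("need 0 < infusion_duration < dosing_interval")

    @property
    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.dosing_interval

    @property
    def rate(self) -> float:
        return self.dose_amount / self.infusion_duration


@dataclass
class PKDataset:
    """Replicate dataset: per-subject covariates and sparse observations.

    ``covariates`` is an ``(n, K)`` DataFrame (one row per subject, constant
    within subject), ``observations`` an ``(n, J)`` array of concentrations at
    ``design.observation_times``.  Every subject shares the dosing design.
    """

    covariates: pd.DataFrame
    observations: np.ndarray
    design: DesignSpec = field(default_factory=DesignSpec)
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        n = len(self.covariates)
        if self.observations.shape != (n, len(self.design.observation_times)):
            raise ValueError("observations shape does not match subjects x times")
        if np.any(self.observations <= 0):
            raise ValueError("concentrations must be positive")
        if self.ids is None:
            self.ids = np.arange(1, n + 1)

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else list(self.covariates.columns)
        return self.covariates[names].to_numpy(dtype=float)


def default_covariate_specs() -> list[CovariateSpec]:
    """The three study covariates (continuous variant)."""
    return [
        CovariateSpec("COVI", mean=70.0, sd=COV_TRUE_SD, role="true-covariate"),
        CovariateSpec("COVII", mean=50.0, sd=15.0, role="correlated"),
        CovariateSpec("COVIII", mean=5.0, sd=2.0, role="noise"),
    ]


def default_design() -> DesignSpec:
    return DesignSpec()


def default_true_params(theta_cov: float = 0.026,
                        cov_name: str = "COVI",
                        cov_mean: float = 70.0,
                        fractional: bool = False,
                        omega2_V: float = 0.0) -> StructuralParams:
    """True simulation parameters: CL 18 L/h, V1 400 L, IIV(CL) 0.1, 15% CV."""
    return StructuralParams(
        theta_CL=18.0, V1=400.0, omega2_CL=0.1, omega2_V=omega2_V,
        sigma_prop=0.15,
        covariate_effects={cov_name: theta_cov},
        covariate_centers={} if fractional else {cov_name: cov_mean},
        fractional=frozenset([cov_name]) if fractional else frozenset(),
    )


def _validate_specs(specs: Sequence[CovariateSpec]) -> None:
    roles = [s.role for s in specs]
    if roles.count("true-covariate") != 1:
        raise ValueError("exactly one covariate must have role 'true-covariate'")


def sample_covariates(specs: Sequence[CovariateSpec], corr: float, n: int,
                      seed) -> pd.DataFrame:
    """Draw ``n`` subjects' covariates.

    ``corr`` is the correlation between the true covariate and the
    ``correlated`` companion (latent scale for dichotomous covariates); noise
    covariates are independent of everything.
    """
    if not 0.0 <= corr < 1.0:
        raise ValueError(f"corr must be in [0, 1), got {corr}")
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    _validate_specs(specs)
    k = len(specs)
    rho = np.eye(k)
    idx = {s.role: i for i, s in enumerate(specs)}
    if "correlated" in idx:
        i, j = idx["true-covariate"], idx["correlated"]
        rho[i, j] = rho[j, i] = corr
    # latent standard-normal draw with the requested correlation structure
    try:
        chol = np.linalg.cholesky(rho)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rho is PD for corr<1
        raise ValueError("implied correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k)) @ chol.T
    cols = {}
    for i, s in enumerate(specs):
        if s.kind == "continuous":
            cols[s.name] = s.mean + s.sd * z[:, i]
        else:
            thresh = stats.norm.ppf(1.0 - s.prevalence)
            cols[s.name] = (z[:, i] > thresh).astype(float)
    return pd.DataFrame(cols)


def simulate_dataset(covariates: pd.DataFrame, design: DesignSpec,
                     true_params: StructuralParams, seed) -> PKDataset:
    """Simulate sparse concentrations for the given covariate table.

    Per subject: eta_CL ~ N(0, omega2_CL) (and eta_V ~ N(0, omega2_V) when
    present), noise-free profile from the analytic model, then one independent
    proportional-error draw per observation (Y = f * (1 + eps)).  eta and eps
    use independent substreams of ``seed`` so engines can be compared on
    identical covariate draws.
    """
    for name in true_params.covariate_effects:
        if name not in covariates.columns:
            raise ValueError(f"covariate table lacks column {name!r}")
    n = len(covariates)
    times = np.asarray(design.observation_times, dtype=float)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    eta_rng, eps_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    eta_cl = eta_rng.normal(0.0, np.sqrt(true_params.omega2_CL), size=n)
    eta_v = (eta_rng.normal(0.0, np.sqrt(true_params.omega2_V), size=n)
             if true_params.omega2_V > 0 else np.zeros(n))
    pred = predict_dataset(true_params,
                           _bare_dataset(covariates, design),
                           np.column_stack([eta_cl, eta_v]))
    eps = eps_rng.normal(0.0, true_params.sigma_prop, size=pred.shape)
    obs = pred * (1.0 + eps)
    return PKDataset(covariates=covariates.reset_index(drop=True),
                     observations=obs, design=design)


def _bare_dataset(covariates: pd.DataFrame, design: DesignSpec) -> PKDataset:
    """Dataset shell with placeholder observations (internal)."""
    n = len(covariates)
    ds = PKDataset.__new__(PKDataset)
    ds.covariates = covariates
    ds.observations = np.ones((n, len(design.observation_times)))
    ds.design = design
    ds.ids = np.arange(1, n + 1)
    return ds


# ---------------------------------------------------------------------------
# NONMEM-layout CSV I/O
# ---------------------------------------------------------------------------

def write_dataset(ds: PKDataset, path) -> None:
    """Write in NONMEM layout: ID TIME AMT RATE EVID DV <covariates>.

    Dosing rows carry EVID=1 with AMT/RATE; observation rows EVID=0 with DV.
    Missing fields are written as ".".
    """
    design = ds.design
    rows = []
    times = np.asarray(design.observation_times, dtype=float)
    cov_names = list(ds.covariates.columns)
    for i in range(ds.n_subjects):
        sid = int(ds.ids[i])
        covs = [ds.covariates[c].iloc[i] for c in cov_names]
        events = [(t, design.dose_amount, design.rate, 1, None)
                  for t in design.dose_times]
        events += [(t, None, None, 0, ds.observations[i, j])
                   for j, t in enumerate(times)]
        events.sort(key=lambda e: (e[0], -e[3]))  # dose before obs at same time
        for t, amt, rate, evid, dv in events:
            rows.append([sid, t, amt, rate, evid, dv] + covs)
    frame = pd.DataFrame(rows, columns=["ID", "TIME", "AMT", "RATE", "EVID", "DV"]
                         + cov_names)
    frame.to_csv(path, index=False, na_rep=".")


def read_dataset(path, design: DesignSpec | None = None) -> PKDataset:
    """Read a NONMEM-layout CSV written by :func:`write_dataset`.

    The dosing design is reconstructed from the EVID=1 rows (and must be
    identical across subjects); malformed rows raise ``ValueError`` naming the
    offending row.
    """
    frame = pd.read_csv(path, na_values=["."])
    required = {"ID", "TIME", "AMT", "RATE", "EVID", "DV"}
    if not required.issubset(frame.columns):
        raise ValueError(f"missing required columns {sorted(required - set(frame.columns))}")
    cov_names = [c for c in frame.columns if c not in required]
    cov_rows, obs_rows, ids = [], [], []
    dose_design = None
    obs_times_ref = None
    for sid, grp in frame.groupby("ID", sort=True):
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            row = grp.index[np.argmax(np.diff(times) < 0) + 1]
            raise ValueError(f"non-monotone TIME within subject {sid} at row {row}")
        doses = grp[grp["EVID"] == 1]
        obs = grp[grp["EVID"] == 0]
        if len(obs) == 0:
            raise ValueError(f"subject {sid} has no observation rows")
        first_dose = doses["TIME"].min() if len(doses) else np.inf
        early = obs[obs["TIME"] <= first_dose]
        if len(early):
            raise ValueError(
                f"observation before any dose for subject {sid} at row {early.index[0]}")
        if obs["DV"].isna().any():
            row = obs.index[obs["DV"].isna().argmax()]
            raise ValueError(f"observation row {row} has missing DV")
        if doses["AMT"].isna().any() or doses["RATE"].isna().any():
            raise ValueError(f"dose row with missing AMT/RATE for subject {sid}")
        dt = doses["TIME"].to_numpy(dtype=float)
        amt = float(doses["AMT"].iloc[0])
        rate = float(doses["RATE"].iloc[0])
        this_design = (tuple(dt), amt, rate)
        if dose_design is None:
            dose_design = this_design
        elif this_design != dose_design:
            raise ValueError(f"subject {sid} has a different dosing design")
        ot = tuple(obs["TIME"].to_numpy(dtype=float))
        if obs_times_ref is None:
            obs_times_ref = ot
        elif ot != obs_times_ref:
            raise ValueError(f"subject {sid} has different observation times")
        cov_rows.append([grp[c].iloc[0] for c in cov_names])
        obs_rows.append(obs["DV"].to_numpy(dtype=float))
        ids.append(int(sid))
    dt, amt, rate = dose_design
    intervals = np.diff(dt)
    if len(dt) > 1 and not np.allclose(intervals, intervals[0]):
        raise ValueError("unevenly spaced doses are not supported")
    interval = float(intervals[0]) if len(dt) > 1 else DesignSpec().dosing_interval
    if design is None:
        design = DesignSpec(dose_amount=amt, infusion_duration=amt / rate,
                            dosing_interval=interval, n_doses=len(dt),
                            observation_times=obs_times_ref)
    return PKDataset(covariates=pd.DataFrame(cov_rows, columns=cov_names),
                     observations=np.asarray(obs_rows), design=design,
                     ids=np.asarray(ids))
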