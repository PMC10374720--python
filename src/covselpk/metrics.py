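"""Summary statistics over replicate covariate-selection outcomes.

Power is the fraction of converged replicates in which the true covariate was
selected (stepwise) or was significant with the largest effect size
(frem_posthoc).  Conditional accuracy and precision of the true-covariate
coefficient are expressed as relative bias and relative root-mean-squared
error over the qualifying replicates only (the denominator N therefore
differs between methods and scenarios):

    rbias(%) = 100/N * sum_i (est_i - true) / true
    rrmse(%) = 100 * sqrt( 1/N * sum_i (est_i - true)^2 / true^2 )

A model counts as predictive when its coefficient lies strictly between zero
and twice the true value, i.e. |(est - true)/true| < 1; the type-I error is
the fraction of replicates flagging the pure-noise covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateOutcome",
    "power",
    "rbias",
    "rrmse",
    "predictive_fraction",
    "type1_error",
    "metrics_table",
]


@dataclass
class ReplicateOutcome:
    """Per-replicate selection outcome for one method."""

    replicate: int
    method: str                       # scm | frem_posthoc | frem_all
    converged: bool = True
    selected_true: bool = False       # the power / selection event
    estimated_coefficient: float | None = None
    noise_selected: bool = False      # cov_III flagged (type-I event)
    covII_selected: bool = False


def _converged(outcomes):
    out = [o for o in outcomes if o.converged]
    if not out:
        raise ValueError("no converged replicates")
    return out


def power(outcomes) -> float:
    """Percent of converged replicates with the selection event."""
    out = _converged(outcomes)
    return 100.0 * sum(o.selected_true for o in out) / len(out)


def rbias(estimates, true_value: float) -> float:
    estimates = np.asarray(list(estimates), dtype=float)
    if true_value == 0:
        raise ValueError("true_value must be nonzero")
    if estimates.size == 0:
        raise ValueError("empty estimate set")
    return float(np.mean((estimates - true_value) / true_value) * 100.0)


def rrmse(estimates, true_value: float) -> float:
    estimates = np.asarray(list(estimates), dtype=float)
    if true_value == 0:
        raise ValueError("true_value must be nonzero")
    if estimates.size == 0:
        raise ValueError("empty estimate set")
    return float(np.sqrt(np.mean((estimates - true_value) ** 2
                                 / true_value ** 2)) * 100.0)


def predictive_fraction(estimates, true_value: float) -> float:
    """Percent of estimates strictly between zero and twice the true value."""
    estimates = np.asarray(list(estimates), dtype=float)
    if estimates.size == 0:
        raise ValueError("empty qualifying set")
    ok = np.abs((estimates - true_value) / true_value) < 1.0
    return float(100.0 * np.mean(ok))


def type1_error(outcomes) -> float:
    """Percent of converged replicates flagging the noise covariate."""
    out = _converged(outcomes)
    return 100.0 * sum(o.noise_selected for o in out) / len(out)


def metrics_table(outcomes, true_value: float, n_subjects: int, corr: float,
                  theta_cov: float) -> pd.DataFrame:
    """Tidy per-method metric rows for one scenario cell.

    Conditional rbias/rrmse/predictive_fraction use the method's qualifying
    set: replicates with the selection event (scm, frem_posthoc) or every
    converged replicate (frem_all).  Empty denominators yield NA, never 0.
    """
    rows = []
    for method in sorted({o.method for o in outcomes}):
        sub = [o for o in outcomes if o.method == method]
        conv = [o for o in sub if o.converged]
        qualifying = ([o for o in conv if o.selected_true]
                      if method != "frem_all" else conv)
        ests = [o.estimated_coefficient for o in qualifying
                if o.estimated_coefficient is not None]
        vals = {
            "power": power(sub) if method != "frem_all" else np.nan,
            "rbias": rbias(ests, true_value) if ests else np.nan,
            "rrmse": rrmse(ests, true_value) if ests else np.nan,
            "predictive_fraction": (predictive_fraction(ests, true_value)
                                    if ests else np.nan),
            "alpha": type1_error(sub) if method != "frem_all" else np.nan,
            "covII_freq": (100.0 * sum(o.covII_selected for o in conv)
                           / len(conv) if conv else np.nan),
        }
        for metric, value in vals.items():
            rows.append({"method": method, "n": n_subjects, "corr": corr,
                         "theta_cov": theta_cov, "metric": metric,
                         "value": value, "n_used": len(ests)
                         if metric in ("rbias", "rrmse", "predictive_fraction")
                         else len(conv)})
    return pd.DataFrame(rows)
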