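"""Stepwise covariate modelling: greedy forward inclusion, backward elimination.

Forward steps add, one at a time, the candidate covariate-parameter relation
with the largest significant drop in objective function (dOFV compared with a
chi-square quantile, df = 1 per relation); once no candidate is significant,
backward elimination removes relations that do not survive a stricter
significance level.  This mirrors common stepwise practice in population PK
model building (forward p < 0.05, backward p < 0.01; or forward-only
p < 0.1 for the statistical head-to-head setting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import foce
from .foce import FitResult, ModelSpec
from .simulate import PKDataset

__all__ = ["ScmSettings", "ScmResult", "forward_step", "backward_step", "run_scm"]

log = logging.getLogger("covselpk")


@dataclass(frozen=True)
class ScmSettings:
    """Significance levels and candidate scope of the stepwise search."""

    forward_p: float = 0.05
    backward_p: float | None = 0.01
    #: candidate (covariate, form) relations on CL; forms as in ModelSpec
    candidates: tuple = (("COVI", "exp"), ("COVII", "exp"), ("COVIII", "exp"))
    iiv_v: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.forward_p < 1.0:
            raise ValueError("forward_p must be in (0, 1)")
        if self.backward_p is not None and self.backward_p >= self.forward_p:
            raise ValueError("backward_p must be stricter than forward_p")


@dataclass
class ScmResult:
    """Outcome of one stepwise search on one dataset."""

    selected: list                      # ordered (covariate, form) relations
    final_fit: FitResult | None
    forward_selected: list              # relations after the forward phase
    trace: pd.DataFrame                 # step, phase, candidate, dofv, decision
    base_converged: bool = True

    def contains(self, covariate: str) -> bool:
        return any(c == covariate for c, _ in self.selected)

    def forward_contains(self, covariate: str) -> bool:
        return any(c == covariate for c, _ in self.forward_selected)

    def coefficient(self, covariate: str) -> float | None:
        if self.final_fit is None or not self.contains(covariate):
            return None
        return float(self.final_fit.estimates[f"beta_{covariate}"])


class _FitCache:
    """One fit per relation-set per dataset; SCM revisits models frequently."""

    def __init__(self, ds: PKDataset, settings: ScmSettings, seed):
        self.ds = ds
        self.settings = settings
        self.seed = seed
        self._cache: dict = {}

    def fit(self, relations: tuple) -> FitResult:
        key = frozenset(relations)
        if key not in self._cache:
            model = ModelSpec(covariate_terms=tuple(relations),
                              iiv_v=self.settings.iiv_v)
            self._cache[key] = foce.fit(model, self.ds, seed=self.seed)
        return self._cache[key]


def forward_step(cache: _FitCache, current: tuple, remaining, rows, step: int):
    """Try each remaining candidate singly; return the best significant one.

    A candidate whose fit fails after retries is treated as non-significant
    for this step (logged), not fatal.  Ties in dOFV break by candidate order.
    """
    settings = cache.settings
    threshold = foce.lrt_threshold(settings.forward_p)
    base = cache.fit(current)
    best = None
    best_dofv = -np.inf
    for cand in remaining:
        ext = cache.fit(current + (cand,))
        if not ext.converged:
            log.debug("forward candidate %s failed to fit; skipped", cand)
            rows.append((step, "forward", cand[0], np.nan, threshold, "fit-failed"))
            continue
        dofv = base.ofv - ext.ofv
        significant = dofv > threshold
        rows.append((step, "forward", cand[0], dofv, threshold,
                     "significant" if significant else "not-significant"))
        if significant and dofv > best_dofv:
            best, best_dofv = cand, dofv
    if best is not None:
        rows.append((step, "forward", best[0], best_dofv, threshold, "added"))
    return best


def backward_step(cache: _FitCache, current: tuple, rows, step: int):
    """Remove the relation whose removal costs least, if below the threshold."""
    settings = cache.settings
    threshold = foce.lrt_threshold(settings.backward_p)
    full = cache.fit(current)
    worst = None
    worst_dofv = np.inf
    for rel in current:
        reduced = tuple(r for r in current if r != rel)
        red_fit = cache.fit(reduced)
        if not red_fit.converged:
            rows.append((step, "backward", rel[0], np.nan, threshold, "fit-failed"))
            continue
        dofv = red_fit.ofv - full.ofv  # OFV increase caused by removal
        retained = dofv > threshold
        rows.append((step, "backward", rel[0], dofv, threshold,
                     "retained" if retained else "removable"))
        if not retained and dofv < worst_dofv:
            worst, worst_dofv = rel, dofv
    if worst is not None:
        rows.append((step, "backward", worst[0], worst_dofv, threshold, "removed"))
    return worst


def run_scm(ds: PKDataset, settings: ScmSettings | None = None, seed=0) -> ScmResult:
    """Full stepwise search: forward to exhaustion, then backward to stability."""
    settings = settings or ScmSettings()
    cache = _FitCache(ds, settings, seed)
    rows: list = []
    base = cache.fit(())
    if not base.converged:
        log.warning("base model failed to converge; replicate unusable")
        return ScmResult(selected=[], final_fit=None, forward_selected=[],
                         trace=_trace_frame(rows), base_converged=False)
    current: tuple = ()
    remaining = list(settings.candidates)
    step = 0
    while remaining:
        step += 1
        best = forward_step(cache, current, remaining, rows, step)
        if best is None:
            break
        current = current + (best,)
        remaining.remove(best)
    forward_selected = list(current)
    if settings.backward_p is not None:
        while current:
            step += 1
            removed = backward_step(cache, current, rows, step)
            if removed is None:
                break
            current = tuple(r for r in current if r != removed)
    final = cache.fit(current)
    return ScmResult(selected=list(current), final_fit=final,
                     forward_selected=forward_selected,
                     trace=_trace_frame(rows))


def _trace_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["step", "phase", "candidate", "dofv",
                                       "threshold", "decision"])
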