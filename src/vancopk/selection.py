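"""Stepwise covariate model building on clearance.

Forward addition accepts, one covariate per step, the candidate giving the
largest OFV drop, provided the drop exceeds 6.64 (chi-square, p < 0.01,
df = 1). Backward elimination then removes, weakest first, any retained
covariate whose removal raises the OFV by no more than 10.83 (p < 0.001).
The renal-function proxies (Scr, CLcr, eGFR) are near-collinear measures of
the same physiology and are treated as mutually exclusive by default: once
one enters, the others leave the candidate pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .estimation import CovariateTerm, FitResult, ModelSpec, OneCompartmentFOCE
from .events import EventTable

__all__ = [
    "CovariateCandidate",
    "StepRecord",
    "SelectionConfig",
    "StepwiseCovariateSelector",
    "DEFAULT_CANDIDATES",
    "forward_step",
    "backward_step",
    "run_stepwise",
]

#: Candidates carry the same functional forms as fitted terms.
CovariateCandidate = CovariateTerm

#: The full candidate set screened in the study: seven continuous
#: covariates (three of them renal-function proxies) and five categorical.
DEFAULT_CANDIDATES = (
    CovariateCandidate("egfr", "continuous", group="renal"),
    CovariateCandidate("clcr", "continuous", group="renal"),
    CovariateCandidate("scr", "continuous", group="renal"),
    CovariateCandidate("age", "continuous"),
    CovariateCandidate("height", "continuous"),
    CovariateCandidate("body_weight", "continuous"),
    CovariateCandidate("bmi", "continuous"),
    CovariateCandidate("sex", "categorical"),
    CovariateCandidate("rrt", "categorical"),
    CovariateCandidate("mannitol", "categorical"),
    CovariateCandidate("meropenem", "categorical"),
    CovariateCandidate("diuretics", "categorical"),
)


@dataclass(frozen=True)
class StepRecord:
    """One bookkeeping row of the stepwise search."""

    step: int
    action: str  # 'add' | 'remove' | 'stop'
    covariate: str | None
    ofv_before: float
    ofv_after: float
    accepted: bool
    candidate_deltas: dict = field(default_factory=dict)

    @property
    def delta_ofv(self) -> float:
        return self.ofv_after - self.ofv_before


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and fit controls for the stepwise search."""

    forward_threshold: float = 6.64  # OFV drop, p < 0.01, df = 1
    backward_threshold: float = 10.83  # OFV rise, p < 0.001, df = 1
    renal_exclusive: bool = True
    max_steps: int = 30
    # screening fits need delta-OFV resolution ~1, far coarser than final
    # estimation, so they run with relaxed tolerances and fewer quadrature
    # nodes
    fit_options: dict = field(
        default_factory=lambda: {
            "compute_se": False,
            "fatol": 0.05,
            "xatol": 3e-3,
            "maxfev": 700,
            "inner_tol": 1e-6,
            "n_quad": 5,
        }
    )


def _fit_spec(spec, data, warm: FitResult | None, config: SelectionConfig) -> FitResult:
    init = None
    if warm is not None:
        # covariates absent from the warm fit are left out of the init so
        # the naive-clearance regression supplies their starting values
        init = {
            "cl_tv": warm.params["cl_tv"],
            "beta": {
                c.name: warm.params[f"beta_{c.name}"]
                for c in spec.covariates
                if f"beta_{c.name}" in warm.params
            },
            "omega_cl": warm.omega_cl,
            "sigma1": warm.sigma.sigma1,
            "sigma2": warm.sigma.sigma2,
        }
    est = OneCompartmentFOCE(
        covariates=spec.covariates, v=spec.v, init=init, **config.fit_options
    )
    est.fit(data)
    return est.result_


def _active_pool(candidates, spec: ModelSpec, config: SelectionConfig):
    pool = [c for c in candidates if c.name not in spec.covariate_names]
    if config.renal_exclusive:
        present_groups = {c.group for c in spec.covariates if c.group}
        pool = [c for c in pool if not (c.group and c.group in present_groups)]
    return pool


def forward_step(
    current: ModelSpec,
    current_fit: FitResult,
    candidates,
    data: EventTable,
    config: SelectionConfig = SelectionConfig(),
    step: int = 0,
):
    """Try every remaining candidate; accept the largest significant drop.

    Returns (StepRecord, new spec, new fit); spec and fit are unchanged when
    nothing is accepted. Ties break by candidate order.
    """
    pool = _active_pool(candidates, current, config)
    if not pool:
        rec = StepRecord(step, "add", None, current_fit.ofv, current_fit.ofv, False)
        return rec, current, current_fit
    deltas, fits = {}, {}
    for cand in pool:
        try:
            res = _fit_spec(current.with_covariate(cand), data, current_fit, config)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"candidate {cand.name} failed to fit: {exc}")
            continue
        if not np.isfinite(res.ofv):
            warnings.warn(f"candidate {cand.name} did not converge; skipped")
            continue
        deltas[cand.name] = res.ofv - current_fit.ofv
        fits[cand.name] = (cand, res)
    if not deltas:
        rec = StepRecord(step, "add", None, current_fit.ofv, current_fit.ofv, False, {})
        return rec, current, current_fit
    best = min(deltas, key=lambda n: (deltas[n], [c.name for c in pool].index(n)))
    accepted = -deltas[best] > config.forward_threshold
    cand, res = fits[best]
    rec = StepRecord(
        step, "add", best, current_fit.ofv,
        res.ofv if accepted else current_fit.ofv, accepted, dict(deltas),
    )
    if accepted:
        return rec, current.with_covariate(cand), res
    return rec, current, current_fit


def backward_step(
    current: ModelSpec,
    current_fit: FitResult,
    data: EventTable,
    config: SelectionConfig = SelectionConfig(),
    step: int = 0,
):
    """Refit with each covariate removed; eliminate the weakest if its
    removal raises OFV by <= the backward threshold."""
    if not current.covariates:
        raise ValueError("backward step requires at least one covariate")
    deltas, fits = {}, {}
    for cand in current.covariates:
        try:
            res = _fit_spec(current.without_covariate(cand.name), data, current_fit, config)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"removal of {cand.name} failed to fit: {exc}")
            continue
        if not np.isfinite(res.ofv):
            warnings.warn(f"removal of {cand.name} did not converge; skipped")
            continue
        deltas[cand.name] = res.ofv - current_fit.ofv
        fits[cand.name] = res
    if not deltas:
        rec = StepRecord(step, "remove", None, current_fit.ofv, current_fit.ofv, False, {})
        return rec, current, current_fit
    weakest = min(deltas, key=deltas.get)
    removed = deltas[weakest] <= config.backward_threshold
    rec = StepRecord(
        step, "remove", weakest, current_fit.ofv,
        fits[weakest].ofv if removed else current_fit.ofv, removed, dict(deltas),
    )
    if removed:
        return rec, current.without_covariate(weakest), fits[weakest]
    return rec, current, current_fit


@dataclass
class StepwiseResult:
    records: list
    final_spec: ModelSpec
    final_fit: FitResult

    @property
    def selected(self) -> list[str]:
        return self.final_spec.covariate_names

    def log_table(self) -> pd.DataFrame:
        """Delimited step log: model description / OFV / delta OFV."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "step": r.step,
                    "action": r.action,
                    "covariate": r.covariate,
                    "ofv_before": r.ofv_before,
                    "ofv_after": r.ofv_after,
                    "delta_ofv": r.delta_ofv,
                    "accepted": r.accepted,
                }
            )
        return pd.DataFrame(rows)


def run_stepwise(
    base: ModelSpec,
    candidates,
    data: EventTable,
    config: SelectionConfig = SelectionConfig(),
    base_fit: FitResult | None = None,
) -> StepwiseResult:
    """Forward addition to exhaustion, then backward elimination to
    stability. Aborts (with the log so far) on add/remove oscillation."""
    if base_fit is None:
        base_fit = _fit_spec(base, data, None, config)
    records: list[StepRecord] = []
    spec, fit_res = base, base_fit
    seen: set[frozenset] = set()
    step = 0
    while step < config.max_steps:
        rec, spec, fit_res = forward_step(spec, fit_res, candidates, data, config, step)
        records.append(rec)
        step += 1
        if not rec.accepted:
            break
        key = frozenset(spec.covariate_names)
        if key in seen:
            warnings.warn("stepwise oscillation detected; aborting")
            return StepwiseResult(records, spec, fit_res)
        seen.add(key)
    while spec.covariates and step < config.max_steps:
        rec, spec, fit_res = backward_step(spec, fit_res, data, config, step)
        records.append(rec)
        step += 1
        if not rec.accepted:
            break
    return StepwiseResult(records, spec, fit_res)


class StepwiseCovariateSelector(BaseEstimator):
    """Scikit-learn-style wrapper around :func:`run_stepwise`."""

    def __init__(
        self,
        candidates=DEFAULT_CANDIDATES,
        forward_threshold: float = 6.64,
        backward_threshold: float = 10.83,
        renal_exclusive: bool = True,
        max_steps: int = 30,
        fit_options: dict | None = None,
    ):
        self.candidates = candidates
        self.forward_threshold = forward_threshold
        self.backward_threshold = backward_threshold
        self.renal_exclusive = renal_exclusive
        self.max_steps = max_steps
        self.fit_options = fit_options

    def fit(self, X: EventTable, y=None) -> "StepwiseCovariateSelector":
        config = SelectionConfig(
            forward_threshold=self.forward_threshold,
            backward_threshold=self.backward_threshold,
            renal_exclusive=self.renal_exclusive,
            max_steps=self.max_steps,
            **({"fit_options": self.fit_options} if self.fit_options else {}),
        )
        result = run_stepwise(ModelSpec(), self.candidates, X, config)
        self.result_ = result
        self.records_ = result.records
        self.selected_covariates_ = result.selected
        self.final_spec_ = result.final_spec
        self.final_fit_ = result.final_fit
        return self
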