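"""Model evaluation: subject-level nonparametric bootstrap and VPC.

Bootstrap resamples whole subjects with replacement (keeping the original
subject count), refits each replicate and summarises the converged ones.
The visual predictive check simulates the fitted model on the dataset's own
design (same subjects, doses and sampling times) and compares percentile
bands of the simulated concentrations with the observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FitResult, ModelSpec, OneCompartmentFOCE, SigmaPair, _Objective
from .events import EventTable

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "vpc"]


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    summary: pd.DataFrame  # per parameter: median, ci2.5, ci97.5, rse_percent
    replicates: pd.DataFrame
    stable: bool

    @property
    def convergence_fraction(self) -> float:
        return self.n_converged / self.n_requested if self.n_requested else 0.0


def bootstrap(
    spec: ModelSpec,
    data: EventTable,
    n_boot: int = 5000,
    seed: int = 0,
    reference_fit: FitResult | None = None,
    fit_options: dict | None = None,
) -> BootstrapResult:
    """Subject-resampling bootstrap of the model parameters.

    Replicate fits warm-start from the reference fit. A result is flagged
    unstable when fewer than 80% of replicates converge.
    """
    rng = np.random.default_rng(seed)
    options = {"compute_se": False, "fatol": 5e-3}
    options.update(fit_options or {})
    if reference_fit is None:
        est = OneCompartmentFOCE(covariates=spec.covariates, v=spec.v, **options)
        reference_fit = est.fit(data).result_
    warm = {
        "cl_tv": reference_fit.params["cl_tv"],
        "beta": {c.name: reference_fit.params[f"beta_{c.name}"] for c in spec.covariates},
        "omega_cl": reference_fit.omega_cl,
        "sigma1": reference_fit.sigma.sigma1,
        "sigma2": reference_fit.sigma.sigma2,
    }
    ids = data.subject_ids
    rows = []
    n_conv = 0
    for b in range(n_boot):
        sample = rng.choice(ids, size=len(ids), replace=True)
        resampled = data.subset(sample)
        try:
            est = OneCompartmentFOCE(
                covariates=spec.covariates, v=spec.v, init=warm, **options
            )
            res = est.fit(resampled).result_
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"bootstrap replicate {b} failed: {exc}")
            continue
        if not res.converged:
            continue
        n_conv += 1
        rows.append({"replicate": b, **res.params, "ofv": res.ofv})
    replicates = pd.DataFrame(rows)
    param_names = [c for c in replicates.columns if c not in ("replicate", "ofv")]
    summary_rows = []
    for name in param_names:
        vals = replicates[name].to_numpy(dtype=float)
        med = float(np.median(vals))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        summary_rows.append(
            {
                "parameter": name,
                "median": med,
                "ci2.5": float(lo),
                "ci97.5": float(hi),
                "rse_percent": 100.0 * sd / abs(med) if med else np.inf,
            }
        )
    summary = pd.DataFrame(summary_rows)
    stable = n_conv >= 0.8 * n_boot
    if not stable:
        warnings.warn(
            f"bootstrap unstable: only {n_conv}/{n_boot} replicates converged"
        )
    return BootstrapResult(
        n_requested=n_boot,
        n_converged=n_conv,
        summary=summary,
        replicates=replicates,
        stable=stable,
    )


@dataclass
class VPCResult:
    bins: pd.DataFrame  # per bin: edges, n_obs, simulated 5/50/95, observed 5/50/95
    observed: pd.DataFrame  # per observation: time-after-dose, conc, PI bounds, inside
    coverage: float  # pooled fraction of observations inside the 90% PI
    n_sim: int

    def export_table(self) -> pd.DataFrame:
        return self.bins.copy()


def vpc(
    spec: ModelSpec,
    fit: FitResult,
    data: EventTable,
    n_sim: int = 10000,
    seed: int = 0,
    n_bins: int = 8,
) -> VPCResult:
    """Visual predictive check of a fitted model on its own design.

    Simulates ``n_sim`` replicates of the dataset (fresh eta and epsilon),
    bins observations by time after the most recent dose (quantile bins) and
    computes 5th/50th/95th percentile bands. Coverage is the pooled fraction
    of observations inside their per-observation 90% prediction interval.
    """
    if not fit.converged:
        raise ValueError("vpc requires a converged fit")
    rng = np.random.default_rng(seed)
    obj = _Objective(spec, data)
    beta = np.array([fit.params[f"beta_{c.name}"] for c in spec.covariates])
    log_cl_typ = np.log(fit.params["cl_tv"]) + (obj.X @ beta if obj.n_beta else 0.0)
    s1, s2 = fit.sigma.sigma1, fit.sigma.sigma2
    omega = fit.omega_cl

    sims = np.empty((n_sim, obj.design.n_obs))
    for r in range(n_sim):
        eta = rng.normal(0.0, omega, size=obj.n_subjects) if omega > 0 else np.zeros(obj.n_subjects)
        pred = obj.design.predict(np.exp(log_cl_typ + eta), spec.v)
        sd = np.sqrt(s2 * s2 + (s1 * pred) ** 2)
        sims[r] = pred + (rng.normal(size=obj.design.n_obs) * sd if sd.max() > 0 else 0.0)

    y = obj.design.y
    tad = obj.design.obs_tad
    if n_sim > 1:
        lo = np.percentile(sims, 5, axis=0)
        hi = np.percentile(sims, 95, axis=0)
    else:
        lo = hi = sims[0]
    inside = (y >= lo) & (y <= hi)
    coverage = float(np.mean(inside))

    # quantile bins on time after dose, merged when degenerate
    edges = np.unique(np.quantile(tad, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        edges = np.array([tad.min() - 1e-9, tad.max() + 1e-9])
    idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    bin_rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            warnings.warn("empty VPC bin merged")
            continue
        sim_vals = sims[:, mask].ravel()
        p5, p50, p95 = np.percentile(sim_vals, [5, 50, 95])
        o5, o50, o95 = np.percentile(y[mask], [5, 50, 95])
        bin_rows.append(
            {
                "tad_low": edges[b],
                "tad_high": edges[b + 1],
                "n_obs": int(mask.sum()),
                "sim_p5": p5,
                "sim_p50": p50,
                "sim_p95": p95,
                "obs_p5": o5,
                "obs_p50": o50,
                "obs_p95": o95,
                "coverage": float(np.mean(inside[mask])),
            }
        )
    observed = pd.DataFrame(
        {"tad": tad, "conc": y, "pi_low": lo, "pi_high": hi, "inside": inside}
    )
    return VPCResult(
        bins=pd.DataFrame(bin_rows), observed=observed, coverage=coverage, n_sim=n_sim
    )
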