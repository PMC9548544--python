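"""Nonlinear mixed-effects estimation for the one-compartment model.

A single log-normal random effect acts on clearance (CL_i = CL_typ * e^eta,
eta ~ N(0, omega^2)); the residual model is combined (variance
sigma2^2 + (sigma1 * C)^2, evaluated at individual predictions, i.e. with
interaction). The marginal likelihood is approximated FOCE-style: the
conditional mode eta_hat_i is located by a one-dimensional bounded search
per subject and a Laplace approximation — refined by adaptive Gauss-Hermite
quadrature centered at the mode — is applied around it. The objective
function value (OFV) is -2 log-likelihood without the n*log(2*pi) constant,
the convention under which only OFV differences are interpreted.

:class:`OneCompartmentFOCE` is a scikit-learn-style estimator: configure in
the constructor, ``fit`` an :class:`~vancopk.events.EventTable`, read
trailing-underscore attributes (``theta_``, ``ofv_``, ``result_``, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .events import EventTable
from .kinetics import PKDesign, compile_design
from .pk import ThetaVector, V_FIXED

__all__ = [
    "SigmaPair",
    "CovariateTerm",
    "ModelSpec",
    "FitResult",
    "OneCompartmentFOCE",
    "neg2ll",
    "fit",
    "cwres",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
_LOGCL_CLIP = 12.0


def _hermite_nodes(n: int):
    if n <= 1:
        return np.array([0.0]), np.array([0.5 * np.log(np.pi)])
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, np.log(w)


@dataclass(frozen=True)
class SigmaPair:
    """Combined residual error: multiplicative CV and additive SD (mg/L)."""

    sigma1: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("sigma components must be non-negative")

    def sd(self, pred):
        return np.sqrt(self.sigma2**2 + (self.sigma1 * np.asarray(pred)) ** 2)


@dataclass(frozen=True)
class CovariateTerm:
    """A covariate acting on CL: centered power (continuous) or
    exponential shift (categorical). ``center=None`` means use the dataset
    median at fit time. ``group`` marks mutually exclusive proxies
    (the renal-function measures)."""

    name: str
    kind: str = "continuous"
    center: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError("kind must be 'continuous' or 'categorical'")
        if self.center is not None and not self.center > 0:
            raise ValueError("centering constant must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """One-compartment infusion model with V fixed and covariates on CL."""

    covariates: tuple = ()
    v: float = V_FIXED

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariates in model spec")

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    def with_covariate(self, term: CovariateTerm) -> "ModelSpec":
        return replace(self, covariates=self.covariates + (term,))

    def without_covariate(self, name: str) -> "ModelSpec":
        return replace(
            self, covariates=tuple(c for c in self.covariates if c.name != name)
        )

    def describe(self) -> str:
        if not self.covariates:
            return "Base model"
        return "CL ~ " + " + ".join(self.covariate_names)


#: Final published model structure (printed centering constants frozen).
FINAL_SPEC = ModelSpec(
    covariates=(
        CovariateTerm("egfr", "continuous", center=115.2, group="renal"),
        CovariateTerm("mannitol", "categorical"),
        CovariateTerm("body_weight", "continuous", center=70.0),
    )
)


@dataclass
class FitResult:
    """Estimates, OFV, uncertainty and diagnostics of one NLME fit."""

    spec: ModelSpec
    theta: ThetaVector
    omega_cl: float
    sigma: SigmaPair
    ofv: float
    params: dict
    se: dict
    rse_percent: dict
    ci95: dict
    eta_modes: pd.Series
    eta_shrinkage: float
    eps_shrinkage: float
    converged: bool
    n_subjects: int
    n_obs: int
    n_evaluations: int = 0
    message: str = ""

    def parameter_table(self) -> pd.DataFrame:
        """Estimate / %RSE / 95% CI table, one row per parameter."""
        rows = []
        for name, est in self.params.items():
            lo, hi = self.ci95.get(name, (np.nan, np.nan))
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "rse_percent": self.rse_percent.get(name, np.nan),
                    "ci95_low": lo,
                    "ci95_high": hi,
                }
            )
        rows.append({"parameter": "v_fixed", "estimate": self.spec.v,
                     "rse_percent": np.nan, "ci95_low": np.nan, "ci95_high": np.nan})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


class _Objective:
    """Compiled FOCE objective for one (spec, dataset) pair."""

    def __init__(
        self,
        spec: ModelSpec,
        table: EventTable,
        eta_bound: float = 6.0,
        inner_tol: float = 1e-8,
        grid_points: int = 9,
        n_quad: int = 9,
    ):
        self.spec = spec
        self.eta_bound = eta_bound
        self.inner_tol = inner_tol
        self.grid_points = grid_points
        self.n_quad = n_quad
        self._quad_x, self._quad_logw = _hermite_nodes(n_quad)
        self._table = table
        obs = table.observations
        include = (~obs["below_lloq"].astype(bool) & obs["conc"].notna()).to_numpy()
        if not include.any():
            raise ValueError("no usable observations (all missing or below LLOQ)")
        self.design: PKDesign = compile_design(table, include)
        self.n_subjects = table.n_subjects
        cov = table.covariate_values()
        cols = []
        self.centers: dict[str, float] = {}
        for term in spec.covariates:
            if term.name not in cov.columns:
                raise KeyError(f"covariate {term.name!r} missing from data")
            x = cov[term.name].to_numpy(dtype=float)
            if term.kind == "continuous":
                center = term.center if term.center is not None else float(np.median(x))
                if not center > 0 or np.any(x <= 0):
                    raise ValueError(f"continuous covariate {term.name!r} must be positive")
                self.centers[term.name] = center
                cols.append(np.log(x / center))
            else:
                cols.append(x)
        self.X = np.column_stack(cols) if cols else np.zeros((self.n_subjects, 0))
        self.n_beta = self.X.shape[1]
        self._obs_per_subject = np.bincount(
            self.design.obs_subject, minlength=self.n_subjects
        )

    # -- likelihood pieces --------------------------------------------------

    def _data_terms(self, eta, log_cl_typ, s1, s2):
        """Per-subject sum of log g^2 + (y-f)^2/g^2 at the given eta."""
        log_cl = np.clip(log_cl_typ + eta, -_LOGCL_CLIP, _LOGCL_CLIP)
        f = self.design.predict(np.exp(log_cl), self.spec.v)
        g2 = s2 * s2 + (s1 * f) ** 2
        np.maximum(g2, 1e-10, out=g2)
        resid = self.design.y - f
        term = np.log(g2) + resid * resid / g2
        return np.bincount(self.design.obs_subject, weights=term, minlength=self.n_subjects)

    def _L(self, eta, log_cl_typ, omega, s1, s2):
        return (
            self._data_terms(eta, log_cl_typ, s1, s2)
            + np.log(omega * omega)
            + (eta / omega) ** 2
        )

    def _solve_eta(self, log_cl_typ, omega, s1, s2):
        """Vectorised conditional modes on [-eta_bound*omega, +eta_bound*omega].

        Coarse grid then golden-section refinement per subject.
        """
        bound = self.eta_bound * omega
        grid = np.linspace(-bound, bound, self.grid_points)
        vals = np.stack([self._L(np.full(self.n_subjects, g), log_cl_typ, omega, s1, s2) for g in grid])
        best = np.argmin(vals, axis=0)
        a = grid[np.maximum(best - 1, 0)]
        b = grid[np.minimum(best + 1, self.grid_points - 1)]
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = self._L(c, log_cl_typ, omega, s1, s2)
        fd = self._L(d, log_cl_typ, omega, s1, s2)
        for _ in range(80):
            if np.max(b - a) < self.inner_tol:
                break
            mask = fc < fd
            b = np.where(mask, d, b)
            a = np.where(mask, a, c)
            c = b - _GOLDEN * (b - a)
            d = a + _GOLDEN * (b - a)
            x_eval = np.where(mask, c, d)
            fx = self._L(x_eval, log_cl_typ, omega, s1, s2)
            fc_old = fc
            fc = np.where(mask, fx, fd)
            fd = np.where(mask, fc_old, fx)
        return 0.5 * (a + b)

    def subject_ofv(self, cl_tv, beta, omega, s1, s2, return_modes=False):
        """Per-subject -2 log marginal likelihood (constant-free) and modes.

        Laplace around the conditional mode, refined by adaptive
        Gauss-Hermite quadrature scaled by the mode curvature (``n_quad``
        nodes; 1 node reproduces the plain Laplace approximation).
        """
        log_cl_typ = np.log(cl_tv) + (self.X @ beta if self.n_beta else 0.0)
        if omega < 1e-6:
            eta = np.zeros(self.n_subjects)
            ofv = self._data_terms(eta, log_cl_typ, s1, s2)
            return (ofv, eta) if return_modes else ofv
        eta = self._solve_eta(log_cl_typ, omega, s1, s2)
        L0 = self._L(eta, log_cl_typ, omega, s1, s2)
        h = max(1e-3 * omega, 1e-7)
        Lp = self._L(eta + h, log_cl_typ, omega, s1, s2)
        Lm = self._L(eta - h, log_cl_typ, omega, s1, s2)
        d2 = (Lp - 2.0 * L0 + Lm) / (h * h)
        np.maximum(d2, 1e-10, out=d2)
        if self.n_quad <= 1:
            ofv = L0 + np.log(0.5 * d2)
            return (ofv, eta) if return_modes else ofv
        # adaptive GH: eta_j = mode + sqrt(2)*sigma_hat*x_j, sigma_hat^2 = 2/L''
        sigma_hat = np.sqrt(2.0 / d2)
        terms = np.empty((self.n_quad, self.n_subjects))
        for j, (x, logw) in enumerate(zip(self._quad_x, self._quad_logw)):
            eta_j = eta + np.sqrt(2.0) * sigma_hat * x
            Lj = self._L(eta_j, log_cl_typ, omega, s1, s2)
            terms[j] = logw - 0.5 * Lj + x * x
        mx = terms.max(axis=0)
        lse = mx + np.log(np.sum(np.exp(terms - mx), axis=0))
        ofv = np.log(2.0 * np.pi) - np.log(2.0 * sigma_hat**2) - 2.0 * lse
        return (ofv, eta) if return_modes else ofv

    def ofv(self, cl_tv, beta, omega, s1, s2) -> float:
        total = float(np.sum(self.subject_ofv(cl_tv, beta, omega, s1, s2)))
        return total if np.isfinite(total) else 1e12

    # -- parameter vector packing ------------------------------------------

    def pack(self, cl_tv, beta, omega, s1, s2):
        return np.concatenate(
            [[np.log(cl_tv)], np.asarray(beta, dtype=float), np.log([omega, s1, s2])]
        )

    def unpack(self, x):
        nb = self.n_beta
        return (
            float(np.exp(x[0])),
            np.asarray(x[1 : 1 + nb], dtype=float),
            float(np.exp(x[1 + nb])),
            float(np.exp(x[2 + nb])),
            float(np.exp(x[3 + nb])),
        )

    def ofv_packed(self, x) -> float:
        return self.ofv(*self.unpack(x))

    def param_names(self) -> list[str]:
        return (
            ["cl_tv"]
            + [f"beta_{c.name}" for c in self.spec.covariates]
            + ["omega_cl", "sigma1", "sigma2"]
        )

    def ofv_natural(self, p) -> float:
        """OFV as a function of the natural-scale parameter vector."""
        nb = self.n_beta
        return self.ofv(p[0], np.asarray(p[1 : 1 + nb]), p[1 + nb], p[2 + nb], p[3 + nb])


# ---------------------------------------------------------------------------
# public functional surface
# ---------------------------------------------------------------------------


def neg2ll(
    spec: ModelSpec,
    params: Mapping,
    data: EventTable,
    eta_bound: float = 6.0,
    inner_tol: float = 1e-8,
) -> float:
    """Constant-free -2 log marginal likelihood (OFV) at given parameters.

    ``params`` maps 'cl_tv', 'omega_cl', 'sigma1', 'sigma2' to floats and
    'beta' to a mapping covariate-name -> coefficient (ordered per spec).
    """
    obj = _Objective(spec, data, eta_bound=eta_bound, inner_tol=inner_tol)
    beta_map = params.get("beta", {})
    beta = np.array([beta_map.get(c.name, 0.0) for c in spec.covariates])
    return obj.ofv(
        params["cl_tv"], beta, params["omega_cl"], params["sigma1"], params["sigma2"]
    )


class OneCompartmentFOCE(BaseEstimator):
    """FOCE estimator for the one-compartment vancomycin model.

    Parameters
    ----------
    covariates : sequence of CovariateTerm
        Covariates entering the clearance model.
    v : float
        Fixed apparent volume of distribution (never estimated).
    init : mapping or None
        Optional initial values ('cl_tv', 'beta' mapping, 'omega_cl',
        'sigma1', 'sigma2'); missing entries fall back to a naive-clearance
        regression for the fixed effects and generic variance starts.
    compute_se : bool
        Whether to compute a finite-difference Hessian for Wald SEs/CIs.
    fatol, xatol, maxfev : float, float, int
        Outer (Nelder-Mead) stopping controls.
    eta_bound : float
        Conditional-mode search bound in units of omega.
    """

    def __init__(
        self,
        covariates: Sequence[CovariateTerm] = (),
        v: float = V_FIXED,
        init: Mapping | None = None,
        compute_se: bool = True,
        fatol: float = 1e-4,
        xatol: float = 1e-4,
        maxfev: int = 2000,
        eta_bound: float = 6.0,
        inner_tol: float = 1e-8,
        n_quad: int = 9,
    ):
        self.covariates = covariates
        self.v = v
        self.init = init
        self.compute_se = compute_se
        self.fatol = fatol
        self.xatol = xatol
        self.maxfev = maxfev
        self.eta_bound = eta_bound
        self.inner_tol = inner_tol
        self.n_quad = n_quad

    # -- sklearn-style API --------------------------------------------------

    def fit(self, X: EventTable, y=None) -> "OneCompartmentFOCE":
        if not isinstance(X, EventTable):
            raise TypeError("X must be an EventTable")
        spec = ModelSpec(covariates=tuple(self.covariates), v=self.v)
        obj = _Objective(
            spec, X, eta_bound=self.eta_bound, inner_tol=self.inner_tol,
            n_quad=self.n_quad,
        )
        x0 = obj.pack(*self._initial_values(obj, X))
        # explicit initial simplex: a fixed minimum step per coordinate so
        # near-zero coefficients are actually explored
        steps = np.maximum(0.05 * np.abs(x0), 0.05)
        simplex = np.vstack([x0] + [x0 + np.eye(len(x0))[i] * steps[i] for i in range(len(x0))])
        res = optimize.minimize(
            obj.ofv_packed,
            x0,
            method="Nelder-Mead",
            options={
                "fatol": self.fatol,
                "xatol": self.xatol,
                "maxfev": self.maxfev,
                "adaptive": True,
                "initial_simplex": simplex,
            },
        )
        cl_tv, beta, omega, s1, s2 = obj.unpack(res.x)
        names = obj.param_names()
        estimates = dict(zip(names, [cl_tv, *beta, omega, s1, s2]))

        se, rse, ci95 = {}, {}, {}
        if self.compute_se:
            se, rse, ci95 = self._wald(obj, estimates)

        subject_ofv, eta = obj.subject_ofv(cl_tv, beta, omega, s1, s2, return_modes=True)
        ofv = float(np.sum(subject_ofv))
        eta_sd = float(np.std(eta, ddof=1)) if len(eta) > 1 else 0.0
        eta_shrink = float(np.clip(1.0 - eta_sd / omega, 0.0, 1.0)) if omega > 0 else 1.0
        iwres = self._iwres(obj, cl_tv, beta, eta, s1, s2)
        eps_shrink = (
            float(np.clip(1.0 - np.std(iwres, ddof=1), 0.0, 1.0)) if len(iwres) > 1 else 1.0
        )

        beta_cont, beta_cat, centering = {}, {}, {}
        for term, b in zip(spec.covariates, beta):
            if term.kind == "continuous":
                beta_cont[term.name] = float(b)
                centering[term.name] = obj.centers[term.name]
            else:
                beta_cat[term.name] = float(b)
        theta = ThetaVector(
            cl_tv=cl_tv,
            v_fixed=spec.v,
            beta_cont=beta_cont,
            beta_cat=beta_cat,
            centering=centering,
        )
        self.spec_ = spec
        self.objective_ = obj
        self.theta_ = theta
        self.omega_cl_ = omega
        self.sigma_ = SigmaPair(s1, s2)
        self.ofv_ = ofv
        self.params_ = estimates
        self.se_ = se
        self.eta_modes_ = pd.Series(eta, index=X.subjects.index, name="eta_mode")
        self.result_ = FitResult(
            spec=spec,
            theta=theta,
            omega_cl=omega,
            sigma=self.sigma_,
            ofv=ofv,
            params=estimates,
            se=se,
            rse_percent=rse,
            ci95=ci95,
            eta_modes=self.eta_modes_,
            eta_shrinkage=eta_shrink,
            eps_shrinkage=eps_shrink,
            converged=bool(res.success and np.isfinite(ofv)),
            n_subjects=X.n_subjects,
            n_obs=obj.design.n_obs,
            n_evaluations=int(res.nfev),
            message=str(res.message),
        )
        self.converged_ = self.result_.converged
        return self

    def predict(self, X: EventTable, kind: str = "pred") -> np.ndarray:
        """Population ('pred') or individual ('ipred') concentration
        predictions at X's observation records."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        obj = _Objective(self.spec_, X, eta_bound=self.eta_bound, inner_tol=self.inner_tol)
        beta = np.array([self.params_[f"beta_{c.name}"] for c in self.spec_.covariates])
        log_cl_typ = np.log(self.params_["cl_tv"]) + (obj.X @ beta if obj.n_beta else 0.0)
        if kind == "pred":
            eta = np.zeros(obj.n_subjects)
        elif kind == "ipred":
            eta = obj._solve_eta(
                log_cl_typ, self.omega_cl_, self.sigma_.sigma1, self.sigma_.sigma2
            )
        else:
            raise ValueError("kind must be 'pred' or 'ipred'")
        return obj.design.predict(np.exp(log_cl_typ + eta), self.spec_.v)

    # -- internals ----------------------------------------------------------

    def _initial_values(self, obj: _Objective, table: EventTable):
        init = dict(self.init or {})
        cl0, beta0 = self._naive_regression(obj, table)
        cl_tv = init.get("cl_tv", cl0)
        beta_map = init.get("beta", {})
        beta = np.array(
            [beta_map.get(c.name, beta0[i]) for i, c in enumerate(obj.spec.covariates)]
        )
        return (
            cl_tv,
            beta,
            init.get("omega_cl", 0.3),
            init.get("sigma1", 0.2),
            init.get("sigma2", 2.0),
        )

    @staticmethod
    def _naive_clearance(table: EventTable) -> pd.Series:
        """Crude per-subject CL from dose rate over mean concentration."""
        obs = table.observations
        usable = obs.loc[~obs["below_lloq"].astype(bool) & obs["conc"].notna()]
        mean_conc = usable.groupby("id")["conc"].mean()
        daily = {}
        for sid, g in table.doses.groupby("id"):
            t = np.sort(g["time"].to_numpy(dtype=float))
            tau = float(np.median(np.diff(t))) if len(t) > 1 else 24.0
            daily[sid] = float(g["amount"].mean()) * 24.0 / tau
        daily = pd.Series(daily)
        cl = (daily / (24.0 * mean_conc)).reindex(table.subjects.index)
        return cl.clip(0.2, 60.0).fillna(8.0)

    def _naive_regression(self, obj: _Objective, table: EventTable):
        cl = self._naive_clearance(table).to_numpy(dtype=float)
        if obj.n_beta == 0:
            return float(np.exp(np.mean(np.log(cl)))), np.zeros(0)
        A = np.column_stack([np.ones(len(cl)), obj.X])
        coef, *_ = np.linalg.lstsq(A, np.log(cl), rcond=None)
        return float(np.exp(np.clip(coef[0], -3, 5))), np.clip(coef[1:], -2.0, 2.0)

    def _wald(self, obj: _Objective, estimates: dict):
        names = obj.param_names()
        p = np.array([estimates[n] for n in names])
        n = len(p)
        h = np.maximum(5e-3 * np.abs(p), 1e-5)
        H = np.empty((n, n))
        f0 = obj.ofv_natural(p)

        def at(delta):
            return obj.ofv_natural(p + delta)

        for i in range(n):
            ei = np.zeros(n)
            ei[i] = h[i]
            H[i, i] = (at(ei) - 2.0 * f0 + at(-ei)) / h[i] ** 2
            for j in range(i + 1, n):
                ej = np.zeros(n)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    at(ei + ej) - at(ei - ej) - at(-ei + ej) + at(-ei - ej)
                ) / (4.0 * h[i] * h[j])
        se, rse, ci95 = {}, {}, {}
        try:
            cov = 2.0 * np.linalg.inv(H)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
        except np.linalg.LinAlgError:
            warnings.warn("singular or indefinite Hessian; standard errors unavailable")
            return {}, {}, {}
        for i, name in enumerate(names):
            s = float(np.sqrt(diag[i]))
            se[name] = s
            rse[name] = 100.0 * s / abs(p[i]) if p[i] != 0 else np.inf
            ci95[name] = (p[i] - 1.96 * s, p[i] + 1.96 * s)
        return se, rse, ci95

    def _iwres(self, obj, cl_tv, beta, eta, s1, s2):
        log_cl_typ = np.log(cl_tv) + (obj.X @ beta if obj.n_beta else 0.0)
        f = obj.design.predict(np.exp(log_cl_typ + eta), obj.spec.v)
        g = np.sqrt(s2 * s2 + (s1 * f) ** 2)
        return (obj.design.y - f) / np.maximum(g, 1e-10)


def fit(
    spec: ModelSpec,
    data: EventTable,
    init: Mapping | None = None,
    **config,
) -> FitResult:
    """Fit a model spec to data; functional wrapper over the estimator."""
    est = OneCompartmentFOCE(covariates=spec.covariates, v=spec.v, init=init, **config)
    est.fit(data)
    return est.result_


def cwres(fit_result: FitResult, data: EventTable) -> pd.DataFrame:
    """Conditional weighted residuals with PRED and IPRED.

    FOCE linearisation: the model is expanded to first order in eta about
    the conditional mode; residuals are whitened by the implied marginal
    covariance (diag residual variance at individual predictions plus the
    rank-one eta term).
    """
    if not fit_result.converged:
        raise ValueError("cwres requires a converged fit")
    obj = _Objective(fit_result.spec, data)
    beta = np.array(
        [fit_result.params[f"beta_{c.name}"] for c in fit_result.spec.covariates]
    )
    cl_tv = fit_result.params["cl_tv"]
    omega = fit_result.omega_cl
    s1, s2 = fit_result.sigma.sigma1, fit_result.sigma.sigma2
    log_cl_typ = np.log(cl_tv) + (obj.X @ beta if obj.n_beta else 0.0)
    if omega > 0:
        eta = obj._solve_eta(log_cl_typ, omega, s1, s2)
    else:
        eta = np.zeros(obj.n_subjects)
    v = fit_result.spec.v
    f_hat = obj.design.predict(np.exp(log_cl_typ + eta), v)
    h = max(1e-4, 1e-3 * max(omega, 1e-3))
    df = (
        obj.design.predict(np.exp(log_cl_typ + eta + h), v)
        - obj.design.predict(np.exp(log_cl_typ + eta - h), v)
    ) / (2.0 * h)
    pred = obj.design.predict(np.exp(log_cl_typ), v)
    g2 = s2 * s2 + (s1 * f_hat) ** 2
    y = obj.design.y

    cwres_vals = np.empty(obj.design.n_obs)
    for i in range(obj.n_subjects):
        idx = np.flatnonzero(obj.design.obs_subject == i)
        if idx.size == 0:
            continue
        J = df[idx]
        E = f_hat[idx] - J * eta[i]
        V = omega * omega * np.outer(J, J) + np.diag(g2[idx])
        Lc = np.linalg.cholesky(V)
        cwres_vals[idx] = np.linalg.solve(Lc, y[idx] - E)
    return pd.DataFrame(
        {
            "id": np.asarray(data.subject_ids)[obj.design.obs_subject],
            "time": obj.design.obs_time,
            "conc": y,
            "pred": pred,
            "ipred": f_hat,
            "cwres": cwres_vals,
        }
    )
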