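"""One-compartment IV-infusion pharmacokinetics and the clearance covariate model.

Vancomycin in adults is eliminated almost entirely by the kidney, so its
clearance (CL) is modelled as a function of renal function (eGFR by CKD-EPI,
or creatinine clearance by Cockcroft-Gault), body weight and co-medication.
The structural model is a one-compartment disposition with zero-order
(infusion) input and first-order elimination; with linear kinetics the
steady-state AUC over 24 h is simply daily dose / CL.

Units used throughout the package: time h, amount mg, concentration mg/L,
volume L, clearance L/h, serum creatinine mg/dL (canonical; see
:func:`scr_umol_to_mgdl`), renal function mL/min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PatientCovariates",
    "RenalFunction",
    "StructuralParams",
    "ThetaVector",
    "DoseEvent",
    "scr_umol_to_mgdl",
    "cockcroft_gault",
    "ckd_epi",
    "typical_cl",
    "individual_cl",
    "concentration",
    "auc24_steady_state",
    "FINAL_THETA",
    "FINAL_OMEGA_CL",
    "BASE_THETA",
    "BASE_OMEGA_CL",
    "V_FIXED",
]

logger = logging.getLogger(__name__)

#: Conversion constant between µmol/L and mg/dL serum creatinine.
UMOL_PER_MGDL = 88.4

#: Fixed apparent volume of distribution (L); not estimable from
#: trough-dominated data, taken from a prior model in the same population.
V_FIXED = 60.2

#: Renal-function values above this (mL/min) are logged as suspicious but
#: never capped (the source cohort contains CLcr up to ~900 mL/min).
RENAL_FLAG_THRESHOLD = 300.0


class DomainError(ValueError):
    """A physically impossible input (non-positive creatinine, dose, ...)."""


class ConfigurationError(KeyError):
    """A covariate referenced by the model is absent from the data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientCovariates:
    """Per-patient covariates; ``scr`` is in mg/dL (canonical unit)."""

    age: float
    sex: str
    body_weight: float
    height: float | None = None
    bmi: float | None = None
    scr: float | None = None
    rrt: bool = False
    mannitol: bool = False
    meropenem: bool = False
    diuretics: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age >= 18:
            raise DomainError(f"age must be >= 18 years, got {self.age}")
        if not self.body_weight > 0:
            raise DomainError("body_weight must be positive")
        if self.scr is not None and not self.scr > 0:
            raise DomainError("scr must be positive (mg/dL)")
        if self.height is not None and not self.height > 0:
            raise DomainError("height must be positive")
        if (
            self.bmi is not None
            and self.height is not None
            and abs(self.bmi - self.body_weight / (self.height / 100.0) ** 2) >= 0.5
        ):
            raise DomainError("bmi inconsistent with body_weight and height")


@dataclass(frozen=True)
class RenalFunction:
    """Creatinine clearance (Cockcroft-Gault) and eGFR (CKD-EPI), mL/min."""

    clcr: float
    egfr: float

    def __post_init__(self) -> None:
        if not (self.clcr > 0 and self.egfr > 0):
            raise DomainError("renal-function values must be strictly positive")


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters; ``k = cl / v`` is derived."""

    cl: float
    v: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0):
            raise DomainError("cl and v must be strictly positive")

    @property
    def k(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.cl / self.v


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects of the clearance model.

    Typical clearance is a product of a population value, centered power
    terms for continuous covariates and exponential shifts for binary ones:

        CL_typ = cl_tv * prod_c (x_c / center_c)^beta_c * exp(sum_b beta_b * flag_b)
    """

    cl_tv: float
    v_fixed: float = V_FIXED
    beta_cont: Mapping[str, float] = field(default_factory=dict)
    beta_cat: Mapping[str, float] = field(default_factory=dict)
    centering: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cl_tv > 0:
            raise DomainError("cl_tv must be positive")
        if not self.v_fixed > 0:
            raise DomainError("v_fixed must be positive")
        for name in self.beta_cont:
            center = self.centering.get(name)
            if center is None or not center > 0:
                raise ConfigurationError(
                    f"continuous covariate {name!r} needs a positive centering constant"
                )


@dataclass(frozen=True)
class DoseEvent:
    """A single IV infusion; 1 h duration is the clinical default."""

    start_time: float
    amount: float
    infusion_duration: float = 1.0
    interval: float | None = None

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise DomainError("dose amount must be positive")
        if not self.infusion_duration > 0:
            raise DomainError("infusion duration must be positive")
        if self.interval is not None and not self.interval > self.infusion_duration:
            raise DomainError("dosing interval must exceed the infusion duration")

    @property
    def end_time(self) -> float:
        return self.start_time + self.infusion_duration

    @property
    def rate(self) -> float:
        """Zero-order infusion rate (mg/h)."""
        return self.amount / self.infusion_duration


#: Final covariate model: CL = 7.98 * (eGFR/115.2)^0.8 * (BW/70)^0.3 * e^A,
#: A = 0.13 with mannitol; V fixed at 60.2 L.
FINAL_THETA = ThetaVector(
    cl_tv=7.98,
    v_fixed=V_FIXED,
    beta_cont={"egfr": 0.8, "body_weight": 0.3},
    beta_cat={"mannitol": 0.13},
    centering={"egfr": 115.2, "body_weight": 70.0},
)

#: SD of the log-normal inter-individual effect on CL in the final model
#: (reported as CV% = 21.45).
FINAL_OMEGA_CL = 0.2145

#: Covariate-free base model.
BASE_THETA = ThetaVector(cl_tv=8.08, v_fixed=V_FIXED)
BASE_OMEGA_CL = 0.4819


# ---------------------------------------------------------------------------
# renal-function equations
# ---------------------------------------------------------------------------


def scr_umol_to_mgdl(scr_umol):
    """Convert serum creatinine from µmol/L to mg/dL (divide by 88.4)."""
    scr_umol = np.asarray(scr_umol, dtype=float)
    if np.any(scr_umol <= 0):
        raise DomainError("serum creatinine must be positive")
    out = scr_umol / UMOL_PER_MGDL
    return float(out) if out.ndim == 0 else out


def cockcroft_gault(age, body_weight, scr, sex):
    """Creatinine clearance (mL/min) by Cockcroft-Gault.

    CLcr = (140 - age) * BW / (Scr * 72), times 0.85 for females.
    ``scr`` in mg/dL; no body-surface normalisation is applied.
    Accepts scalars or arrays (``sex`` as 'male'/'female' or an array thereof).
    """
    age = np.asarray(age, dtype=float)
    body_weight = np.asarray(body_weight, dtype=float)
    scr = np.asarray(scr, dtype=float)
    if np.any(scr <= 0):
        raise DomainError("serum creatinine must be positive")
    female = np.asarray(sex) == "female"
    clcr = (140.0 - age) * body_weight / (scr * 72.0)
    clcr = np.where(female, clcr * 0.85, clcr)
    _flag_extreme(clcr, "CLcr")
    return float(clcr) if clcr.ndim == 0 else clcr


def ckd_epi(scr, age, sex):
    """Estimated GFR (mL/min) by the CKD-EPI equation.

    eGFR = 144 * (Scr/a)^b * 0.993^age with sex-specific a and a
    creatinine-branch-specific exponent b:
    female a=0.7 (b=-0.329 for Scr<=0.7, -1.209 above);
    male a=0.9 (b=-0.411 for Scr<=0.9, -1.210 above).
    The two branches agree at Scr=a, so eGFR is continuous in Scr.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise DomainError("serum creatinine must be positive")
    female = np.asarray(sex) == "female"
    a = np.where(female, 0.7, 0.9)
    b = np.where(
        female,
        np.where(scr <= 0.7, -0.329, -1.209),
        np.where(scr <= 0.9, -0.411, -1.210),
    )
    egfr = 144.0 * (scr / a) ** b * 0.993**age
    _flag_extreme(egfr, "eGFR")
    return float(egfr) if egfr.ndim == 0 else egfr


def ckd_epi_inverse(egfr, age, sex):
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``egfr``.

    Continuity of the equation at Scr = a makes the inverse well defined:
    eGFR >= 144*0.993^age corresponds to the below-breakpoint branch.
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0):
        raise DomainError("eGFR must be positive")
    female = np.asarray(sex) == "female"
    a = np.where(female, 0.7, 0.9)
    r = egfr / (144.0 * 0.993**age)
    b = np.where(female, np.where(r >= 1.0, -0.329, -1.209), np.where(r >= 1.0, -0.411, -1.210))
    scr = a * r ** (1.0 / b)
    return float(scr) if scr.ndim == 0 else scr


def renal_function(cov: PatientCovariates) -> RenalFunction:
    """Both renal-function measures for one patient (requires ``scr``)."""
    if cov.scr is None:
        raise ConfigurationError("serum creatinine is required for renal function")
    return RenalFunction(
        clcr=cockcroft_gault(cov.age, cov.body_weight, cov.scr, cov.sex),
        egfr=ckd_epi(cov.scr, cov.age, cov.sex),
    )


def _flag_extreme(values, label: str) -> None:
    n = int(np.sum(np.asarray(values) > RENAL_FLAG_THRESHOLD))
    if n:
        logger.info("%d %s value(s) exceed %g mL/min (not capped)", n, label, RENAL_FLAG_THRESHOLD)


# ---------------------------------------------------------------------------
# clearance model
# ---------------------------------------------------------------------------


def typical_cl_from_values(theta: ThetaVector, values: Mapping[str, float]) -> float:
    """Typical clearance for a covariate mapping (names -> values/flags)."""
    cl = theta.cl_tv
    for name, beta in theta.beta_cont.items():
        if name not in values:
            raise ConfigurationError(f"covariate {name!r} missing from values")
        cl *= (values[name] / theta.centering[name]) ** beta
    shift = 0.0
    for name, beta in theta.beta_cat.items():
        if name not in values:
            raise ConfigurationError(f"covariate {name!r} missing from values")
        shift += beta * float(values[name])
    return cl * math.exp(shift)


def typical_cl(theta: ThetaVector, rf: RenalFunction, cov: PatientCovariates) -> float:
    """Population typical clearance (L/h) for one patient."""
    values = {
        "egfr": rf.egfr,
        "clcr": rf.clcr,
        "age": cov.age,
        "body_weight": cov.body_weight,
        "height": cov.height,
        "bmi": cov.bmi,
        "scr": cov.scr,
        "sex": 1.0 if cov.sex == "female" else 0.0,
        "rrt": float(cov.rrt),
        "mannitol": float(cov.mannitol),
        "meropenem": float(cov.meropenem),
        "diuretics": float(cov.diuretics),
    }
    values = {k: v for k, v in values.items() if v is not None}
    return typical_cl_from_values(theta, values)


def individual_cl(typical: float, eta: float) -> float:
    """Individual clearance CL_i = CL_typ * e^eta (log-normal IIV)."""
    if not typical > 0:
        raise DomainError("typical clearance must be positive")
    return typical * math.exp(eta)


# ---------------------------------------------------------------------------
# concentration-time course
# ---------------------------------------------------------------------------


def concentration(doses: Sequence[DoseEvent], params: StructuralParams, t):
    """Plasma concentration (mg/L) at time(s) ``t`` by superposition.

    Each infusion contributes ``(R0/CL) * (1 - e^{-k*(t-t0)})`` while running
    and decays mono-exponentially from its end-of-infusion value afterwards.
    Contributions are linear in dose amount; times before the first dose
    give zero.
    """
    k = params.k
    if not k > 0:
        raise DomainError("elimination rate constant must be positive")
    t = np.asarray(t, dtype=float)
    c = np.zeros_like(t)
    for d in doses:
        dt_on = np.clip(np.minimum(t, d.end_time) - d.start_time, 0.0, None)
        dt_off = np.clip(t - d.end_time, 0.0, None)
        c += (d.rate / params.cl) * (1.0 - np.exp(-k * dt_on)) * np.exp(-k * dt_off)
    return float(c) if c.ndim == 0 else c


def auc24_steady_state(daily_dose: float, cl: float) -> float:
    """Steady-state AUC over 24 h (h*mg/L): daily dose / clearance."""
    if not (daily_dose > 0 and cl > 0):
        raise DomainError("daily dose and clearance must be positive")
    return daily_dose / cl
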