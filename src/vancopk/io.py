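"""Dataset serialisation, run configuration and the pipeline driver.

Datasets use a NONMEM-style event layout: one row per dose or observation,
columns ID, TIME, AMT, DUR (or RATE), DV, EVID, MDV, BLQ plus per-subject
covariates (AGE, SEX with 0=male/1=female, WT, HT, BMI, SCR, RRT, MANN,
MERO, DIUR). Times are hours from each subject's first dose, doses mg,
concentrations mg/L. Serum creatinine is stored in mg/dL; a µmol/L column
is converted on read (divide by 88.4).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pk
from .cohort import CohortConfig, generate_cohort, simulate_observations
from .dosing import build_dose_table
from .estimation import FINAL_SPEC, ModelSpec, OneCompartmentFOCE, SigmaPair
from .evaluation import bootstrap, vpc
from .events import EventTable
from .selection import DEFAULT_CANDIDATES, SelectionConfig, run_stepwise

__all__ = ["read_dataset", "write_dataset", "RunConfig", "run_pipeline"]

_COV_MAP = {
    "AGE": "age",
    "WT": "body_weight",
    "HT": "height",
    "BMI": "bmi",
    "SCR": "scr",
    "RRT": "rrt",
    "MANN": "mannitol",
    "MERO": "meropenem",
    "DIUR": "diuretics",
}
_REQUIRED = ["ID", "TIME", "AMT", "DV", "EVID", "SEX", "AGE", "WT", "SCR"]
_KNOWN = set(_REQUIRED) | set(_COV_MAP) | {"DUR", "RATE", "MDV", "BLQ"}


def write_dataset(table: EventTable, path, header_comment: str | None = None) -> None:
    """Write an event table as a NONMEM-style CSV."""
    rows = []
    for sid, cov in table.subjects.iterrows():
        base = {
            "AGE": cov["age"],
            "SEX": 1 if cov["sex"] == "female" else 0,
            "WT": cov["body_weight"],
            "HT": cov["height"],
            "BMI": cov["bmi"],
            "SCR": cov["scr"],
            "RRT": int(cov["rrt"]),
            "MANN": int(cov["mannitol"]),
            "MERO": int(cov["meropenem"]),
            "DIUR": int(cov["diuretics"]),
        }
        for _, d in table.doses[table.doses["id"] == sid].iterrows():
            rows.append(
                {"ID": sid, "TIME": d["time"], "AMT": d["amount"], "DUR": d["duration"],
                 "DV": np.nan, "EVID": 1, "MDV": 1, "BLQ": 0, **base}
            )
        for _, o in table.observations[table.observations["id"] == sid].iterrows():
            rows.append(
                {"ID": sid, "TIME": o["time"], "AMT": np.nan, "DUR": np.nan,
                 "DV": o["conc"], "EVID": 0, "MDV": int(pd.isna(o["conc"])),
                 "BLQ": int(bool(o["below_lloq"])), **base}
            )
    frame = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable")
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)
    if table.eta_true is not None:
        # truth sidecar for simulated cohorts: the per-subject random effect
        sidecar = path.with_suffix(path.suffix + ".eta")
        truth = pd.DataFrame({"ID": table.subjects.index, "ETA_CL": table.eta_true.to_numpy()})
        with open(sidecar, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            truth.to_csv(fh, index=False)


def read_dataset(path, scr_unit: str = "mg/dL") -> EventTable:
    """Read a NONMEM-style CSV into an :class:`EventTable`.

    ``scr_unit`` declares the unit of the SCR column ('mg/dL' or 'umol/L');
    µmol/L values are converted to the canonical mg/dL.
    """
    if scr_unit not in ("mg/dL", "umol/L"):
        raise ValueError("scr_unit must be 'mg/dL' or 'umol/L'")
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    unknown = set(frame.columns) - _KNOWN
    if unknown:
        warnings.warn(f"ignoring unknown columns: {sorted(unknown)}")
    if "DUR" not in frame.columns:
        if "RATE" in frame.columns:
            frame["DUR"] = frame["AMT"] / frame["RATE"]
        else:
            frame["DUR"] = np.nan
    elif "RATE" in frame.columns:
        need = frame["DUR"].isna() & frame["RATE"].notna()
        frame.loc[need, "DUR"] = frame.loc[need, "AMT"] / frame.loc[need, "RATE"]
    frame["DUR"] = frame["DUR"].fillna(1.0)  # 1 h infusion default
    if "MDV" not in frame.columns:
        frame["MDV"] = (frame["EVID"] != 0).astype(int)
    if "BLQ" not in frame.columns:
        frame["BLQ"] = 0

    for sid, g in frame.groupby("ID"):
        t = g["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < -1e-9):
            raise ValueError(f"non-monotone event times for subject {sid}")

    obs_rows = frame[frame["EVID"] == 0]
    bad = obs_rows[obs_rows["DV"].isna() & (obs_rows["MDV"] == 0)]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} observation row(s) with missing DV "
            f"(rows {list(bad.index)})"
        )
        frame = frame.drop(index=bad.index)

    scale = 1.0 / pk.UMOL_PER_MGDL if scr_unit == "umol/L" else 1.0
    subj_rows = []
    for sid, g in frame.groupby("ID"):
        r = g.iloc[0]
        scr = float(r["SCR"]) * scale
        age = float(r["AGE"])
        sex = "female" if int(r["SEX"]) == 1 else "male"
        weight = float(r["WT"])
        subj_rows.append(
            {
                "id": sid,
                "age": age,
                "sex": sex,
                "body_weight": weight,
                "height": float(r.get("HT", np.nan)),
                "bmi": float(r.get("BMI", np.nan)),
                "scr": scr,
                "rrt": bool(r.get("RRT", 0)),
                "mannitol": bool(r.get("MANN", 0)),
                "meropenem": bool(r.get("MERO", 0)),
                "diuretics": bool(r.get("DIUR", 0)),
                "clcr": pk.cockcroft_gault(age, weight, scr, sex),
                "egfr": pk.ckd_epi(scr, age, sex),
            }
        )
    subjects = pd.DataFrame(subj_rows).set_index("id")
    doses = frame[frame["EVID"] == 1][["ID", "TIME", "AMT", "DUR"]].rename(
        columns={"ID": "id", "TIME": "time", "AMT": "amount", "DUR": "duration"}
    ).reset_index(drop=True)
    obs = frame[frame["EVID"] == 0][["ID", "TIME", "DV", "BLQ"]].rename(
        columns={"ID": "id", "TIME": "time", "DV": "conc", "BLQ": "below_lloq"}
    ).reset_index(drop=True)
    obs["below_lloq"] = obs["below_lloq"].astype(bool)
    return EventTable(subjects=subjects, doses=doses, observations=obs)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run configuration (reproducibility contract)."""

    output_dir: str = "vancopk_run"
    dataset: str | None = None  # path; if None, a cohort is simulated
    scr_unit: str = "mg/dL"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "fit": True,
            "stepwise": False,
            "bootstrap": False,
            "vpc": False,
            "dose_table": True,
        }
    )
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    n_boot: int = 5000
    n_sim_vpc: int = 10000
    n_sim_dose: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages and write delimited reports.

    Order: load/generate data -> base fit -> stepwise -> final fit ->
    bootstrap -> VPC -> dose table. Every output embeds the config hash and
    seed so a rerun with the same config is reproducible.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"vancopk config_hash={config.config_hash()} seed={config.seed}"
    manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                "seed": config.seed, "outputs": []}

    def save(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# {tag}\n")
            frame.to_csv(fh, index=False)
        manifest["outputs"].append(name)

    needs_data = any(
        config.stages.get(s) for s in ("fit", "stepwise", "bootstrap", "vpc")
    )
    data = None
    if needs_data:
        if config.dataset:
            data = read_dataset(config.dataset, scr_unit=config.scr_unit)
        else:
            cc = CohortConfig(**{"seed": config.seed, **config.cohort})
            data = simulate_observations(
                generate_cohort(cc), seed=config.seed + 1, lloq=cc.lloq, uloq=cc.uloq
            )
            write_dataset(data, out / "dataset.csv", header_comment=tag)
            manifest["outputs"].append("dataset.csv")

    final_fit = None
    final_spec = FINAL_SPEC
    try:
        if config.stages.get("stepwise"):
            result = run_stepwise(ModelSpec(), DEFAULT_CANDIDATES, data, SelectionConfig())
            save(result.log_table(), "step_log.csv")
            final_spec, final_fit = result.final_spec, result.final_fit
        if config.stages.get("fit"):
            est = OneCompartmentFOCE(covariates=final_spec.covariates, v=final_spec.v)
            final_fit = est.fit(data).result_
            save(final_fit.parameter_table(), "parameters.csv")
        if config.stages.get("bootstrap"):
            boot = bootstrap(
                final_spec, data, n_boot=config.n_boot, seed=config.seed,
                reference_fit=final_fit,
            )
            save(boot.summary, "bootstrap.csv")
        if config.stages.get("vpc"):
            v = vpc(final_spec, final_fit, data, n_sim=config.n_sim_vpc, seed=config.seed)
            save(v.bins, "vpc.csv")
            manifest["vpc_coverage"] = v.coverage
        if config.stages.get("dose_table"):
            theta = final_fit.theta if final_fit is not None else pk.FINAL_THETA
            omega = final_fit.omega_cl if final_fit is not None else pk.FINAL_OMEGA_CL
            table = build_dose_table(
                theta=theta, omega_cl=omega, n_sim=config.n_sim_dose, seed=config.seed
            )
            save(table, "dose_table.csv")
    except Exception as exc:
        manifest["failure"] = repr(exc)
        with open(out / "run.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(out / "run.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
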