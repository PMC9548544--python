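"""The longitudinal dosing/observation container shared by every stage.

An :class:`EventTable` holds one cohort: a per-subject covariate frame, a
dose-event frame and an observation frame, mirroring the NONMEM-style
dataset layout used by :mod:`vancopk.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["EventTable", "SUBJECT_COLUMNS"]

SUBJECT_COLUMNS = [
    "age",
    "sex",
    "body_weight",
    "height",
    "bmi",
    "scr",
    "rrt",
    "mannitol",
    "meropenem",
    "diuretics",
    "clcr",
    "egfr",
]

DOSE_COLUMNS = ["id", "time", "amount", "duration"]
OBS_COLUMNS = ["id", "time", "conc", "below_lloq"]


@dataclass
class EventTable:
    """Cohort data: subjects (indexed by id), dose events and observations.

    ``observations.conc`` is NaN for a design-only table (doses and sampling
    times scheduled, concentrations not yet simulated or measured).
    ``eta_true`` optionally records the simulated inter-individual effect per
    subject for recovery tests.
    """

    subjects: pd.DataFrame
    doses: pd.DataFrame
    observations: pd.DataFrame
    eta_true: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in SUBJECT_COLUMNS if c not in self.subjects.columns]
        if missing:
            raise ValueError(f"subjects frame missing columns: {missing}")
        for frame, cols, name in (
            (self.doses, DOSE_COLUMNS, "doses"),
            (self.observations, OBS_COLUMNS, "observations"),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise ValueError(f"{name} frame missing columns: {missing}")
        ids = set(self.subjects.index)
        if not set(self.doses["id"]).issubset(ids):
            raise ValueError("dose events reference unknown subject ids")
        if not set(self.observations["id"]).issubset(ids):
            raise ValueError("observations reference unknown subject ids")
        if len(self.observations) and set(self.observations["id"]) != ids:
            first_dose = self.doses.groupby("id")["time"].min()
            obs_ids = set(self.observations["id"])
            if ids - obs_ids:
                raise ValueError("every subject must have at least one observation")
        # observation times never precede the subject's first dose
        if len(self.observations) and len(self.doses):
            first_dose = self.doses.groupby("id")["time"].min()
            t0 = self.observations["id"].map(first_dose).to_numpy(dtype=float)
            if np.any(self.observations["time"].to_numpy(dtype=float) < t0 - 1e-9):
                raise ValueError("observation before the subject's first dose")

    # -- convenience --------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects.index.to_numpy()

    def covariate_values(self) -> pd.DataFrame:
        """Numeric covariate frame (sex/flags as 0/1) used by the CL model."""
        out = self.subjects.copy()
        out["sex"] = (out["sex"] == "female").astype(float)
        for col in ("rrt", "mannitol", "meropenem", "diuretics"):
            out[col] = out[col].astype(float)
        return out

    def subset(self, ids) -> "EventTable":
        """New table containing the given subject ids (in their given order,
        duplicates allowed; duplicated subjects are relabelled 0..n-1)."""
        ids = list(ids)
        subj = self.subjects.loc[ids].reset_index(drop=True)
        subj.index.name = self.subjects.index.name or "id"
        dose_groups = {i: g for i, g in self.doses.groupby("id")}
        obs_groups = {i: g for i, g in self.observations.groupby("id")}
        doses, obs = [], []
        for new_id, old_id in enumerate(ids):
            d = dose_groups[old_id].copy()
            d["id"] = new_id
            doses.append(d)
            o = obs_groups[old_id].copy()
            o["id"] = new_id
            obs.append(o)
        eta = None
        if self.eta_true is not None:
            eta = pd.Series(self.eta_true.loc[ids].to_numpy(), index=subj.index)
        return EventTable(
            subjects=subj,
            doses=pd.concat(doses, ignore_index=True),
            observations=pd.concat(obs, ignore_index=True),
            eta_true=eta,
        )

    def with_observations(self, observations: pd.DataFrame, eta_true=None) -> "EventTable":
        return replace(self, observations=observations, eta_true=eta_true)
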