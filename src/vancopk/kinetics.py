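"""Vectorised closed-form kinetics over a whole cohort.

The estimation, simulation and evaluation stages all need plasma
concentrations at every scheduled observation for an arbitrary vector of
per-subject clearances. :class:`PKDesign` pre-compiles the (observation,
dose) superposition structure of an :class:`~vancopk.events.EventTable` into
flat arrays so that one prediction pass is a handful of numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventTable

__all__ = ["PKDesign", "compile_design"]


@dataclass
class PKDesign:
    """Flattened superposition structure for fast repeated prediction."""

    n_subjects: int
    n_obs: int
    obs_subject: np.ndarray  # (n_obs,) subject index per observation
    obs_time: np.ndarray
    y: np.ndarray  # observed concentration (NaN if not simulated yet)
    obs_tad: np.ndarray  # time after start of most recent dose
    pair_obs: np.ndarray  # (n_pairs,) observation index per (obs, dose) pair
    pair_dt_on: np.ndarray  # time spent infusing before the observation
    pair_dt_off: np.ndarray  # time since end of infusion (0 while running)
    pair_rate: np.ndarray  # infusion rate mg/h

    def predict(self, cl: np.ndarray, v: float) -> np.ndarray:
        """Concentration at every observation given per-subject CL (L/h)."""
        cl = np.asarray(cl, dtype=float)
        k = cl / v
        k_pair = k[self.obs_subject[self.pair_obs]]
        cl_pair = cl[self.obs_subject[self.pair_obs]]
        contrib = (
            (self.pair_rate / cl_pair)
            * -np.expm1(-k_pair * self.pair_dt_on)
            * np.exp(-k_pair * self.pair_dt_off)
        )
        return np.bincount(self.pair_obs, weights=contrib, minlength=self.n_obs)


def compile_design(table: EventTable, include_mask: np.ndarray | None = None) -> PKDesign:
    """Compile an event table; ``include_mask`` selects observations (e.g. to
    drop below-LLOQ records from a likelihood)."""
    subj_index = {sid: i for i, sid in enumerate(table.subject_ids)}
    obs = table.observations
    if include_mask is not None:
        obs = obs.loc[np.asarray(include_mask, dtype=bool)]
    obs = obs.reset_index(drop=True)

    obs_subject = obs["id"].map(subj_index).to_numpy(dtype=np.int64)
    obs_time = obs["time"].to_numpy(dtype=float)
    y = obs["conc"].to_numpy(dtype=float)

    dose_groups = {subj_index[i]: g for i, g in table.doses.groupby("id")}
    pair_obs, pair_dt_on, pair_dt_off, pair_rate = [], [], [], []
    obs_tad = np.zeros(len(obs))
    for j in range(len(obs)):
        g = dose_groups.get(obs_subject[j])
        if g is None:
            continue
        t = obs_time[j]
        t0 = g["time"].to_numpy(dtype=float)
        dur = g["duration"].to_numpy(dtype=float)
        amt = g["amount"].to_numpy(dtype=float)
        started = t0 <= t
        prior = t0[started]
        obs_tad[j] = t - prior.max() if prior.size else np.nan
        t0, dur, amt = t0[started], dur[started], amt[started]
        t1 = t0 + dur
        pair_obs.append(np.full(len(t0), j, dtype=np.int64))
        pair_dt_on.append(np.clip(np.minimum(t, t1) - t0, 0.0, None))
        pair_dt_off.append(np.clip(t - t1, 0.0, None))
        pair_rate.append(amt / dur)

    def cat(parts, dtype=float):
        return (
            np.concatenate(parts).astype(dtype) if parts else np.empty(0, dtype=dtype)
        )

    return PKDesign(
        n_subjects=table.n_subjects,
        n_obs=len(obs),
        obs_subject=obs_subject,
        obs_time=obs_time,
        y=y,
        obs_tad=obs_tad,
        pair_obs=cat(pair_obs, np.int64),
        pair_dt_on=cat(pair_dt_on),
        pair_dt_off=cat(pair_dt_off),
        pair_rate=cat(pair_rate),
    )
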