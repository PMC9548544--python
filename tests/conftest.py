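import numpy as np
import pandas as pd
import pytest

import vancopk as v
from vancopk.estimation import FitResult, SigmaPair


TRUE_PARAMS = {
    "cl_tv": 7.98,
    "beta_egfr": 0.8,
    "beta_mannitol": 0.13,
    "beta_body_weight": 0.3,
    "omega_cl": 0.2145,
    "sigma1": 0.25,
    "sigma2": 1.51,
}


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject cohort simulated from the final model."""
    return v.simulate_cohort(v.CohortConfig(n_subjects=40, seed=7))


@pytest.fixture(scope="session")
def mid_cohort():
    """150-subject cohort simulated from the final model."""
    return v.simulate_cohort(v.CohortConfig(n_subjects=150, seed=13))


@pytest.fixture(scope="session")
def toy_table():
    """Deterministic 5-subject fixture for likelihood-oracle checks."""
    return v.simulate_cohort(v.CohortConfig(n_subjects=5, seed=42))


def true_fit_result(table, params=None) -> FitResult:
    """A FitResult holding known (e.g. data-generating) parameters, for
    diagnostics that need a 'fitted' model without running the optimiser."""
    p = dict(TRUE_PARAMS)
    if params:
        p.update(params)
    spec = v.FINAL_SPEC
    theta = v.ThetaVector(
        cl_tv=p["cl_tv"],
        beta_cont={"egfr": p["beta_egfr"], "body_weight": p["beta_body_weight"]},
        beta_cat={"mannitol": p["beta_mannitol"]},
        centering={"egfr": 115.2, "body_weight": 70.0},
    )
    return FitResult(
        spec=spec,
        theta=theta,
        omega_cl=p["omega_cl"],
        sigma=SigmaPair(p["sigma1"], p["sigma2"]),
        ofv=np.nan,
        params=p,
        se={},
        rse_percent={},
        ci95={},
        eta_modes=pd.Series(0.0, index=table.subjects.index),
        eta_shrinkage=np.nan,
        eps_shrinkage=np.nan,
        converged=True,
        n_subjects=table.n_subjects,
        n_obs=table.n_observations,
    )
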