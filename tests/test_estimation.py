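"""FOCE objective, fitting and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import vancopk as v
from vancopk.estimation import ModelSpec, OneCompartmentFOCE, SigmaPair, _Objective, cwres, neg2ll
from vancopk.cohort import CohortConfig, generate_cohort, simulate_observations

from conftest import TRUE_PARAMS, true_fit_result
from oracles import gauss_hermite_ofv


def _single_obs_table(conc=10.0, cl=8.0):
    subjects = pd.DataFrame(
        {
            "age": [50.0], "sex": ["male"], "body_weight": [70.0],
            "height": [170.0], "bmi": [70.0 / 1.7**2], "scr": [0.8],
            "rrt": [False], "mannitol": [False], "meropenem": [False],
            "diuretics": [False], "clcr": [100.0], "egfr": [100.0],
        },
        index=pd.Index([0], name="id"),
    )
    doses = pd.DataFrame({"id": [0] * 5, "time": [0.0, 12, 24, 36, 48],
                          "amount": [1000.0] * 5, "duration": [1.0] * 5})
    obs = pd.DataFrame({"id": [0], "time": [59.9], "conc": [conc], "below_lloq": [False]})
    return v.EventTable(subjects=subjects, doses=doses, observations=obs)


class TestNeg2ll:
    def test_degenerate_gaussian_single_observation(self):
        table = _single_obs_table(conc=9.0)
        spec = ModelSpec()
        sigma2 = 1.7
        params = {"cl_tv": 8.0, "omega_cl": 0.0, "sigma1": 0.0, "sigma2": sigma2}
        got = neg2ll(spec, params, table)
        doses = [v.DoseEvent(t, 1000.0) for t in [0.0, 12, 24, 36, 48]]
        pred = v.concentration(doses, v.StructuralParams(cl=8.0, v=60.2), 59.9)
        expected = np.log(sigma2**2) + (9.0 - pred) ** 2 / sigma2**2
        assert got == pytest.approx(expected, rel=1e-9)

    def test_omega_zero_limit_continuous(self, toy_table):
        spec = v.FINAL_SPEC
        beta = {"egfr": 0.8, "mannitol": 0.13, "body_weight": 0.3}
        base = {"cl_tv": 7.98, "beta": beta, "sigma1": 0.25, "sigma2": 1.51}
        at_zero = neg2ll(spec, {**base, "omega_cl": 0.0}, toy_table)
        near_zero = neg2ll(spec, {**base, "omega_cl": 1e-5}, toy_table)
        assert near_zero == pytest.approx(at_zero, abs=0.01)

    def test_subject_permutation_invariance(self, small_cohort):
        params = {
            "cl_tv": 7.98,
            "beta": {"egfr": 0.8, "mannitol": 0.13, "body_weight": 0.3},
            "omega_cl": 0.2145, "sigma1": 0.25, "sigma2": 1.51,
        }
        a = neg2ll(v.FINAL_SPEC, params, small_cohort)
        rng = np.random.default_rng(1)
        shuffled = small_cohort.subset(rng.permutation(small_cohort.subject_ids))
        b = neg2ll(v.FINAL_SPEC, params, shuffled)
        assert abs(a - b) < 1e-6

    def test_matches_gauss_hermite_oracle(self, toy_table):
        obj = _Objective(v.FINAL_SPEC, toy_table)
        beta = np.array([0.8, 0.13, 0.3])
        args = (7.98, beta, 0.2145, 0.25, 1.51)
        assert obj.ofv(*args) == pytest.approx(
            gauss_hermite_ofv(obj, *args, n_nodes=2000), abs=0.05
        )


class TestFit:
    def test_noise_free_identifiability(self):
        cohort = generate_cohort(CohortConfig(n_subjects=120, seed=31))
        data = simulate_observations(
            cohort, theta=v.BASE_THETA, omega_cl=0.0,
            sigma=SigmaPair(0.0, 0.05), seed=1,
        )
        est = OneCompartmentFOCE(covariates=(), compute_se=False)
        est.fit(data)
        assert est.converged_
        assert est.params_["cl_tv"] == pytest.approx(8.08, rel=1e-3)

    def test_fitted_attributes_and_clone(self, small_cohort):
        est = OneCompartmentFOCE(
            covariates=v.FINAL_SPEC.covariates, compute_se=False,
            fatol=0.05, xatol=3e-3, maxfev=1200, n_quad=5,
        )
        cloned = clone(est)  # sklearn param contract
        assert cloned.get_params()["maxfev"] == 1200
        est.fit(small_cohort)
        r = est.result_
        assert r.converged and np.isfinite(r.ofv)
        assert set(r.params) == {
            "cl_tv", "beta_egfr", "beta_mannitol", "beta_body_weight",
            "omega_cl", "sigma1", "sigma2",
        }
        assert len(est.eta_modes_) == small_cohort.n_subjects
        assert 0.0 <= r.eta_shrinkage <= 1.0 and 0.0 <= r.eps_shrinkage <= 1.0
        preds = est.predict(small_cohort)
        ipreds = est.predict(small_cohort, kind="ipred")
        assert preds.shape == ipreds.shape == (small_cohort.n_observations,)

    def test_wald_intervals_bracket_estimates(self, mid_cohort):
        est = OneCompartmentFOCE(covariates=v.FINAL_SPEC.covariates)
        est.fit(mid_cohort)
        r = est.result_
        assert r.se, "standard errors should be available"
        for name, (lo, hi) in r.ci95.items():
            assert lo < r.params[name] < hi
            assert r.rse_percent[name] == pytest.approx(
                100 * r.se[name] / abs(r.params[name]), rel=1e-9
            )


class TestCwres:
    def test_degenerate_equals_scaled_residual(self):
        table = _single_obs_table(conc=9.0)
        fit_res = true_fit_result(
            table,
            {"cl_tv": 8.0, "beta_egfr": 0.0, "beta_mannitol": 0.0,
             "beta_body_weight": 0.0, "omega_cl": 0.0, "sigma1": 0.0,
             "sigma2": 2.0},
        )
        out = cwres(fit_res, table)
        doses = [v.DoseEvent(t, 1000.0) for t in [0.0, 12, 24, 36, 48]]
        pred = v.concentration(doses, v.StructuralParams(cl=8.0, v=60.2), 59.9)
        assert out.cwres.iloc[0] == pytest.approx((9.0 - pred) / 2.0, rel=1e-6)

    def test_calibrated_under_true_model(self):
        # assay-range truncation is disabled so the check isolates the
        # residual whitening itself
        cohort = generate_cohort(CohortConfig(n_subjects=560, seed=23))
        data = simulate_observations(cohort, seed=24, lloq=-np.inf, uloq=np.inf)
        out = cwres(true_fit_result(data), data)
        assert len(out) >= 800
        assert abs(out.cwres.mean()) < 0.1
        assert 0.9 < out.cwres.std() < 1.1

    def test_misspecification_inflates_mean(self):
        data = v.simulate_cohort(CohortConfig(n_subjects=300, seed=29))
        good = cwres(true_fit_result(data), data)
        bad_params = dict(TRUE_PARAMS)
        bad_params.update({"beta_egfr": 0.0})  # omit the dominant covariate
        bad = cwres(true_fit_result(data, bad_params), data)
        assert abs(bad.cwres.mean()) > abs(good.cwres.mean())
        assert bad.cwres.std() > good.cwres.std()
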