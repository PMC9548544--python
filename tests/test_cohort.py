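"""Synthetic cohort generation and concentration simulation."""

import numpy as np
import pandas as pd
import pytest

import vancopk as v
from vancopk.cohort import CohortConfig, generate_cohort, simulate_observations
from vancopk.estimation import SigmaPair
from vancopk.kinetics import compile_design


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(CohortConfig(n_subjects=5000, seed=99))


class TestGenerateCohort:
    def test_seeded_determinism_byte_identical(self):
        a = generate_cohort(CohortConfig(n_subjects=30, seed=5))
        b = generate_cohort(CohortConfig(n_subjects=30, seed=5))
        assert a.subjects.to_csv() == b.subjects.to_csv()
        assert a.doses.to_csv() == b.doses.to_csv()
        assert a.observations.to_csv() == b.observations.to_csv()

    def test_single_subject(self):
        t = generate_cohort(CohortConfig(n_subjects=1, seed=3))
        assert t.n_subjects == 1 and t.n_observations >= 1

    def test_comedication_frequency_at_study_size(self):
        t = generate_cohort(CohortConfig(n_subjects=560, seed=0))
        assert abs(t.subjects.mannitol.mean() - 0.6032) < 0.05

    def test_marginals_match_targets(self, big_cohort):
        s = big_cohort.subjects
        n = len(s)
        # mean within 3 standard errors of the target for each marginal
        for col, mean, sd in [
            ("age", 52.41, 15.11),
            ("body_weight", 69.74, 13.05),
            ("height", 167.88, 7.98),
            ("egfr", 112.74, 30.91),
        ]:
            assert abs(s[col].mean() - mean) < 3 * sd / np.sqrt(n), col
        assert abs(s["egfr"].std() - 30.91) < 0.1 * 30.91
        for col, p in [
            ("mannitol", 0.6032),
            ("meropenem", 0.7132),
            ("diuretics", 0.1595),
            ("rrt", 0.0272),
        ]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(s[col].mean() - p) < 3 * se, col
        frac_male = (s["sex"] == "male").mean()
        p = 370 / 560
        assert abs(frac_male - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_covariates_internally_consistent(self, big_cohort):
        s = big_cohort.subjects
        np.testing.assert_allclose(
            s.bmi, s.body_weight / (s.height / 100) ** 2, rtol=1e-9
        )
        np.testing.assert_allclose(
            s.egfr, v.ckd_epi(s.scr.to_numpy(), s.age.to_numpy(), s.sex.to_numpy()),
            rtol=1e-9,
        )
        assert (s.scr > 0).all()

    def test_dose_renal_function_coupling(self, big_cohort):
        daily = (
            big_cohort.doses.groupby("id")
            .apply(
                lambda g: g.amount.iloc[0] * 24.0 / np.median(np.diff(np.sort(g.time)))
                if len(g) > 1
                else g.amount.iloc[0],
                include_groups=False,
            )
        )
        egfr = big_cohort.subjects.egfr
        high = daily[egfr >= 120].mean()
        low = daily[egfr < 40].mean()
        assert high > 1.5 * low

    def test_sampling_design(self):
        t = generate_cohort(CohortConfig(n_subjects=400, seed=21))
        obs, doses = t.observations, t.doses
        # every subject observed at least once, never before its first dose
        assert set(obs.id) == set(t.subjects.index)
        # every observation follows at least five administered doses
        for sid, g in obs.groupby("id"):
            dose_times = doses.loc[doses.id == sid, "time"].to_numpy()
            for tt in g.time:
                assert (dose_times < tt).sum() >= 5
        # troughs dominate: most samples sit within the lead window of a dose
        design = compile_design(t)
        tau = doses.groupby("id").apply(
            lambda g: np.median(np.diff(np.sort(g.time))), include_groups=False
        )
        tads = design.obs_tad
        intervals = obs.id.map(tau).to_numpy()
        trough_like = np.abs(tads - (intervals - 0.05)) < 1e-6
        assert trough_like.mean() > 0.83

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(age=(50, 10, (80, 20)))


class TestSimulateObservations:
    def test_noise_free_equals_closed_form(self, small_cohort):
        sim = simulate_observations(
            small_cohort, omega_cl=0.0, sigma=SigmaPair(0.0, 0.0), seed=1
        )
        for sid in sim.subject_ids[:10]:
            row = sim.subjects.loc[sid]
            cl = v.typical_cl_from_values(
                v.FINAL_THETA,
                {
                    "egfr": row.egfr,
                    "body_weight": row.body_weight,
                    "mannitol": float(row.mannitol),
                },
            )
            doses = [
                v.DoseEvent(r.time, r.amount, r.duration)
                for r in sim.doses[sim.doses.id == sid].itertuples()
            ]
            o = sim.observations[sim.observations.id == sid]
            expected = v.concentration(
                doses, v.StructuralParams(cl=cl, v=60.2), o.time.to_numpy()
            )
            np.testing.assert_allclose(o.conc.to_numpy(), expected, rtol=1e-9)

    def test_seeded_determinism(self, small_cohort):
        a = simulate_observations(small_cohort, seed=4)
        b = simulate_observations(small_cohort, seed=4)
        assert a.observations.to_csv() == b.observations.to_csv()
        assert not a.observations.conc.equals(
            simulate_observations(small_cohort, seed=5).observations.conc
        )

    def test_error_model_self_consistency(self):
        # whitened residuals are ~N(0,1); at high predictions the CV of the
        # log-ratio approaches sigma1
        cohort = generate_cohort(CohortConfig(n_subjects=800, seed=17))
        sigma = SigmaPair(0.25, 1.51)
        sim = simulate_observations(
            cohort, omega_cl=0.0, sigma=sigma, seed=2, lloq=-np.inf, uloq=np.inf
        )
        noise_free = simulate_observations(
            cohort, omega_cl=0.0, sigma=SigmaPair(0.0, 0.0), seed=2
        )
        pred = noise_free.observations.conc.to_numpy()
        obs = sim.observations.conc.to_numpy()
        z = (obs - pred) / sigma.sd(pred)
        assert abs(z.mean()) < 0.1 and 0.9 < z.std() < 1.1
        hi = pred > 12.0
        assert hi.sum() > 50
        log_ratio_sd = np.std(np.log(obs[hi] / pred[hi]))
        assert log_ratio_sd == pytest.approx(sigma.sigma1, rel=0.25)

    def test_assay_range_enforced(self, small_cohort):
        sim = simulate_observations(small_cohort, seed=9)
        conc = sim.observations.conc
        assert (conc > 0).all() and (conc <= 90.0).all()

    def test_eta_truth_recorded(self, small_cohort):
        sim = simulate_observations(small_cohort, seed=3)
        assert sim.eta_true is not None and len(sim.eta_true) == sim.n_subjects
        assert abs(sim.eta_true).max() < 6 * 0.2145
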