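"""Renal-function equations, the clearance covariate model and closed-form
one-compartment kinetics."""

import math

import numpy as np
import pytest

import vancopk as v
from vancopk.pk import DomainError

from oracles import ode_concentration


class TestCreatinineConversion:
    @pytest.mark.parametrize(
        "umol, mgdl",
        [(88.4, 1.0), (64.87, 64.87 / 88.4), (957.5, 957.5 / 88.4)],
    )
    def test_conversion(self, umol, mgdl):
        assert v.scr_umol_to_mgdl(umol) == pytest.approx(mgdl, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            v.scr_umol_to_mgdl(0.0)


class TestCockcroftGault:
    @pytest.mark.parametrize(
        "age, bw, scr, sex, expected",
        [
            (40, 72, 1.0, "male", 100.0),
            (40, 72, 1.0, "female", 85.0),
            (52, 70, 0.7339, "male", (140 - 52) * 70 / (0.7339 * 72)),
        ],
    )
    def test_examples(self, age, bw, scr, sex, expected):
        assert v.cockcroft_gault(age, bw, scr, sex) == pytest.approx(expected, rel=1e-9)

    def test_rejects_nonpositive_scr(self):
        with pytest.raises(DomainError):
            v.cockcroft_gault(40, 70, 0.0, "male")


class TestCkdEpi:
    def test_age_zero_reference(self):
        # hypothetical age 0 at the female breakpoint: both factors are 1
        assert v.ckd_epi(0.7, 0, "female") == pytest.approx(144.0, rel=1e-12)

    @pytest.mark.parametrize(
        "scr, age, sex, expected",
        [
            # below-breakpoint male branch, b = -0.411
            (0.7339, 52, "male", 144 * (0.7339 / 0.9) ** -0.411 * 0.993**52),
            # above-breakpoint male branch, b = -1.210
            (2.0, 52, "male", 144 * (2.0 / 0.9) ** -1.210 * 0.993**52),
            # female branches
            (0.5, 40, "female", 144 * (0.5 / 0.7) ** -0.329 * 0.993**40),
            (1.4, 40, "female", 144 * (1.4 / 0.7) ** -1.209 * 0.993**40),
        ],
    )
    def test_branches(self, scr, age, sex, expected):
        assert v.ckd_epi(scr, age, sex) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("sex, a", [("female", 0.7), ("male", 0.9)])
    def test_continuity_at_breakpoint(self, sex, a):
        below = v.ckd_epi(a * (1 - 1e-12), 50, sex)
        above = v.ckd_epi(a * (1 + 1e-12), 50, sex)
        assert below == pytest.approx(above, rel=1e-9)
        assert v.ckd_epi(a, 50, sex) == pytest.approx(144 * 0.993**50, rel=1e-12)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        egfr = rng.uniform(5, 240, size=200)
        age = rng.uniform(18, 89, size=200)
        sex = np.where(rng.random(200) < 0.5, "male", "female")
        scr = v.pk.ckd_epi_inverse(egfr, age, sex)
        np.testing.assert_allclose(v.ckd_epi(scr, age, sex), egfr, rtol=1e-9)


class TestTypicalClearance:
    def test_centered_reference_value(self):
        values = {"egfr": 115.2, "body_weight": 70.0, "mannitol": 0.0}
        assert v.typical_cl_from_values(v.FINAL_THETA, values) == 7.98

    @pytest.mark.parametrize(
        "egfr, bw, mann",
        [(90.0, 65.0, 1.0), (15.0, 65.0, 1.0), (45.0, 85.0, 0.0)],
    )
    def test_matches_direct_evaluation(self, egfr, bw, mann):
        expected = 7.98 * (egfr / 115.2) ** 0.8 * (bw / 70) ** 0.3 * math.exp(0.13 * mann)
        got = v.typical_cl_from_values(
            v.FINAL_THETA, {"egfr": egfr, "body_weight": bw, "mannitol": mann}
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_renal_function_and_weight(self):
        base = {"egfr": 100.0, "body_weight": 70.0, "mannitol": 0.0}
        cl0 = v.typical_cl_from_values(v.FINAL_THETA, base)
        assert v.typical_cl_from_values(v.FINAL_THETA, {**base, "egfr": 140.0}) > cl0
        assert v.typical_cl_from_values(v.FINAL_THETA, {**base, "body_weight": 90.0}) > cl0

    def test_mannitol_multiplier_exact(self):
        base = {"egfr": 88.0, "body_weight": 64.0, "mannitol": 0.0}
        ratio = v.typical_cl_from_values(
            v.FINAL_THETA, {**base, "mannitol": 1.0}
        ) / v.typical_cl_from_values(v.FINAL_THETA, base)
        assert ratio == pytest.approx(math.exp(0.13), rel=1e-12)

    def test_missing_covariate_raises(self):
        with pytest.raises(KeyError):
            v.typical_cl_from_values(v.FINAL_THETA, {"egfr": 100.0})


class TestIndividualClearance:
    @pytest.mark.parametrize(
        "typical, eta, expected",
        [(7.98, 0.0, 7.98), (7.98, math.log(2), 15.96), (7.2952, -0.2, 7.2952 * math.exp(-0.2))],
    )
    def test_lognormal_scaling(self, typical, eta, expected):
        assert v.individual_cl(typical, eta) == pytest.approx(expected, rel=1e-9)


class TestConcentration:
    PARAMS = v.StructuralParams(cl=7.98, v=60.2)

    def test_no_doses_and_pre_dose_zero(self):
        assert v.concentration([], self.PARAMS, 5.0) == 0.0
        doses = [v.DoseEvent(10.0, 1000.0)]
        assert v.concentration(doses, self.PARAMS, 2.0) == 0.0

    def test_linearity_in_dose(self):
        rng = np.random.default_rng(3)
        doses = [v.DoseEvent(12.0 * i, 1000.0) for i in range(6)]
        doubled = [v.DoseEvent(d.start_time, 2 * d.amount) for d in doses]
        t = rng.uniform(0, 80, size=25)
        np.testing.assert_allclose(
            v.concentration(doubled, self.PARAMS, t),
            2.0 * v.concentration(doses, self.PARAMS, t),
            rtol=1e-12,
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_ode_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_doses = rng.integers(1, 21)
        starts = np.sort(rng.uniform(0, 60, size=n_doses))
        doses = [
            v.DoseEvent(float(s), float(rng.uniform(250, 1500)), float(rng.uniform(0.5, 2.0)))
            for s in starts
        ]
        params = v.StructuralParams(cl=float(rng.uniform(2, 15)), v=60.2)
        t = np.sort(rng.uniform(0.5, 75, size=15))
        closed = v.concentration(doses, params, t)
        ode = ode_concentration(doses, params, t)
        np.testing.assert_allclose(closed, ode, rtol=1e-6, atol=1e-9)

    def test_steady_state_trough_matches_geometric_series(self):
        # after many q12h doses the trough approaches the geometric limit
        params = self.PARAMS
        k = params.k
        tau, n = 12.0, 60
        doses = [v.DoseEvent(tau * i, 1000.0) for i in range(n)]
        trough_t = n * tau
        expected_single = v.concentration([v.DoseEvent(0.0, 1000.0)], params, tau)
        expected = expected_single / (1.0 - math.exp(-k * tau))
        assert v.concentration(doses, params, trough_t) == pytest.approx(expected, rel=1e-6)


class TestAuc24:
    @pytest.mark.parametrize(
        "daily, cl", [(2900.0, 7.2952), (1000.0, 1000.0), (1800.0, 5.0)]
    )
    def test_identity(self, daily, cl):
        assert v.auc24_steady_state(daily, cl) == pytest.approx(daily / cl, rel=1e-12)

    def test_matches_trapezoidal_integration(self):
        params = v.StructuralParams(cl=7.2952, v=60.2)
        tau, n = 12.0, 80  # long past steady state
        doses = [v.DoseEvent(tau * i, 1450.0) for i in range(n + 2)]
        t = np.arange(tau * n, tau * n + 24.0 + 0.01, 0.01)
        auc_num = np.trapezoid(v.concentration(doses, params, t), t)
        assert auc_num == pytest.approx(
            v.auc24_steady_state(2900.0, params.cl), rel=5e-3
        )
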