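"""One-compartment oral model: closed forms against independent numeric oracles."""

import numpy as np
import pytest
from scipy import integrate

import bepopk as bp
from bepopk.pk_core import (
    DoseRegimen,
    StructuralParams,
    auc,
    auc_trapezoid,
    conc_multi_dose,
    conc_single_dose,
    exposure,
    tmax_cmax,
)


def ode_profile(p, dose, times):
    """Brute-force oracle: integrate the gut/central linear system."""

    def rhs(t, y):
        return [-p.ka * y[0], p.ka * y[0] - p.ke * y[1]]

    sol = integrate.solve_ivp(
        rhs,
        (p.alag, max(times[-1], p.alag + 1e-9)),
        [dose * p.f, 0.0],
        t_eval=np.maximum(times, p.alag),
        rtol=1e-10,
        atol=1e-12,
    )
    c = 1000.0 * sol.y[1] / p.v
    return np.where(times <= p.alag, 0.0, c)


def random_params(rng):
    return StructuralParams(
        ka=rng.uniform(0.5, 8.0),
        cl=rng.uniform(5.0, 50.0),
        v=rng.uniform(20.0, 200.0),
        alag=rng.uniform(0.0, 0.5),
    )


class TestConcSingleDose:
    def test_zero_at_and_before_lag(self, typical_adult):
        assert conc_single_dose(typical_adult, 10.0, 0.2) == 0.0
        assert conc_single_dose(typical_adult, 10.0, typical_adult.alag) == 0.0

    def test_matches_ode_oracle_on_random_draws(self):
        rng = np.random.default_rng(11)
        times = np.linspace(0.0, 24.0, 40)
        for _ in range(10):
            p = random_params(rng)
            ours = conc_single_dose(p, 10.0, times)
            ref = ode_profile(p, 10.0, times)
            scale = ref.max()
            assert np.all(np.abs(ours - ref) < 1e-6 * scale)

    def test_dose_linearity(self, typical_adult):
        t = np.linspace(0.3, 24, 25)
        np.testing.assert_allclose(
            conc_single_dose(typical_adult, 20.0, t),
            2.0 * conc_single_dose(typical_adult, 10.0, t),
            rtol=1e-14,
        )

    def test_ka_equal_ke_limit_is_continuous(self):
        ke = 0.3
        near = StructuralParams(ka=ke * (1 + 1e-9), cl=ke * 50.0, v=50.0, alag=0.0)
        just_outside = StructuralParams(ka=ke * (1 + 1e-7), cl=ke * 50.0, v=50.0, alag=0.0)
        t = np.array([1.0, 3.0, 8.0])
        np.testing.assert_allclose(
            conc_single_dose(near, 10, t), conc_single_dose(just_outside, 10, t), rtol=1e-5
        )

    def test_rejects_invalid_inputs(self, typical_adult):
        with pytest.raises(ValueError):
            StructuralParams(ka=-1, cl=28, v=103)
        with pytest.raises(ValueError):
            StructuralParams(ka=4.2, cl=28, v=103, f=1.5)
        with pytest.raises(ValueError):
            conc_single_dose(typical_adult, 10.0, -1.0)


class TestPeak:
    def test_typical_adult_peak_matches_grid_oracle(self, typical_adult):
        # independent oracle: refine the maximum on a fine grid
        grid = np.linspace(0.27, 5.0, 200001)
        c = conc_single_dose(typical_adult, 10.0, grid)
        i = np.argmax(c)
        tmax, cmax = tmax_cmax(typical_adult, 10.0)
        assert tmax == pytest.approx(grid[i], abs=1e-4)
        assert cmax == pytest.approx(c[i], rel=1e-8)
        # frozen values from the oracle
        assert tmax == pytest.approx(0.9658, abs=2e-4)
        assert cmax == pytest.approx(80.357, rel=1e-4)

    def test_child_scaled_peak(self):
        p = StructuralParams(ka=4.21, cl=10.94, v=29.43, alag=0.27)
        _, cmax = tmax_cmax(p, 1.0)
        assert cmax == pytest.approx(26.86, rel=2e-3)  # grid oracle value

    def test_lag_shifts_tmax_but_not_cmax(self):
        with_lag = StructuralParams(ka=4.21, cl=28.0, v=103.0, alag=0.27)
        no_lag = StructuralParams(ka=4.21, cl=28.0, v=103.0, alag=0.0)
        t1, c1 = tmax_cmax(with_lag, 10.0)
        t0, c0 = tmax_cmax(no_lag, 10.0)
        assert c1 == pytest.approx(c0, rel=1e-12)
        assert t1 - t0 == pytest.approx(0.27, abs=1e-12)


class TestAuc:
    def test_auc_inf_is_dose_over_clearance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_params(rng)
            assert auc(p, 10.0) == pytest.approx(1000.0 * 10.0 / p.cl, rel=1e-14)

    def test_finite_auc_matches_quadrature(self, typical_adult):
        ref, _ = integrate.quad(
            lambda t: conc_single_dose(typical_adult, 10.0, t), 0, 24, limit=200
        )
        assert auc(typical_adult, 10.0, 24.0) == pytest.approx(ref, rel=1e-8)
        assert auc(typical_adult, 10.0, 24.0) == pytest.approx(356.54, rel=1e-4)
        assert auc(typical_adult, 10.0) == pytest.approx(357.14, rel=1e-4)

    def test_zero_before_lag_and_trapezoid_limit(self, typical_adult):
        assert auc(typical_adult, 10.0, 0.1) == 0.0
        fine = auc_trapezoid(typical_adult, 10.0, np.linspace(0, 24, 200001))
        assert fine == pytest.approx(auc(typical_adult, 10.0, 24.0), rel=1e-6)

    def test_exposure_bundle_is_consistent(self, typical_adult):
        m = exposure(typical_adult, 10.0)
        assert m.auc_last <= m.auc_inf
        assert m.tmax > typical_adult.alag
        assert m.cmax > 0


class TestMultiDose:
    def test_single_dose_regimen_equals_single_dose(self, typical_adult):
        t = np.linspace(0, 24, 30)
        np.testing.assert_allclose(
            conc_multi_dose(typical_adult, DoseRegimen(amount=10.0), t),
            conc_single_dose(typical_adult, 10.0, t),
            rtol=1e-14,
        )

    def test_zero_before_first_dose_plus_lag(self, typical_adult):
        r = DoseRegimen(amount=10.0, interval=12.0, n_doses=5)
        assert conc_multi_dose(typical_adult, r, 0.2) == 0.0

    def test_steady_state_matches_closed_form(self, typical_adult):
        # oracle: analytic steady-state oral solution with accumulation factors
        p, tau = typical_adult, 12.0
        r = DoseRegimen(amount=10.0, interval=tau, n_doses=21)
        t_after = np.linspace(0.5, 11.5, 12)
        ke = p.ke
        coef = 1000.0 * 10.0 * p.f * p.ka / (p.v * (p.ka - ke))
        tt = t_after - p.alag
        css = coef * (
            np.exp(-ke * tt) / (1 - np.exp(-ke * tau))
            - np.exp(-p.ka * tt) / (1 - np.exp(-p.ka * tau))
        )
        ours = conc_multi_dose(p, r, 20 * tau + t_after)
        np.testing.assert_allclose(ours, css, rtol=1e-3)

    def test_steady_state_interval_auc_equals_single_dose_auc_inf(self, typical_adult):
        # superposition conservation after >= 15 intervals
        r = DoseRegimen(amount=10.0, interval=12.0, n_doses=20)
        grid = np.linspace(19 * 12.0, 20 * 12.0, 20001)
        auc_interval = np.trapezoid(conc_multi_dose(typical_adult, r, grid), grid)
        assert auc_interval == pytest.approx(auc(typical_adult, 10.0), rel=1e-3)
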