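"""Relaxation-rate fitting and derived quantities."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrdyn import rates
from nmrdyn.rates import SpinLockSettings


class TestMonoexponential:
    def test_noiseless_recovery(self):
        t = np.linspace(0.1, 1.0, 8)
        y = 100.0 * np.exp(-2.0 * t)
        fit = rates.fit_monoexponential(t, y)
        assert fit.rate == pytest.approx(2.0, rel=1e-8)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-8)

    def test_constant_trace_flagged(self):
        fit = rates.fit_monoexponential([0.1, 0.2, 0.3], [50.0, 50.0, 50.0])
        assert "degenerate" in fit.flags

    def test_noisy_rate_within_three_sigma(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0.05, 1.5, 10)
        y = 100.0 * np.exp(-1.5 * t) + rng.normal(0, 1.0, t.shape)
        fit = rates.fit_monoexponential(t, y, sigma=1.0, n_mc=200, seed=1)
        assert abs(fit.rate - 1.5) < 3 * fit.rate_error
        assert fit.rate_error > 0

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            rates.fit_monoexponential([0.1, 0.2], [10, 5])


class TestR2FromR1rho:
    def test_on_resonance_reduces_to_r1rho(self):
        r2, _ = rates.r2_from_r1rho(8.0, 1.5, SpinLockSettings(2000.0, 0.0))
        assert r2 == 8.0

    def test_45_degree_tilt(self):
        # omega = Omega: theta = 45 deg, R2 = 10/0.5 - 2/1 = 18
        r2, _ = rates.r2_from_r1rho(10.0, 2.0, SpinLockSettings(500.0, 500.0))
        assert r2 == pytest.approx(18.0, rel=1e-12)

    def test_r1_zero_limit(self):
        sl = SpinLockSettings(500.0, 500.0)
        r2, _ = rates.r2_from_r1rho(10.0, 0.0, sl)
        assert r2 == pytest.approx(10.0 / math.sin(math.atan2(500, 500)) ** 2)

    def test_undefined_angle(self):
        with pytest.raises(ValueError):
            SpinLockSettings(0.0, 0.0)


class TestHetNOE:
    def test_error_propagation(self):
        res = rates.hetnoe(100.0, 100.0, 1.0, 1.0)
        assert res.noe_ratio == 1.0
        assert res.noe_error == pytest.approx(math.sqrt(2) / 100, rel=1e-6)

    def test_zero_sigma(self):
        res = rates.hetnoe(80.0, 100.0)
        assert (res.noe_ratio, res.noe_error) == (0.8, 0.0)

    def test_negative_noe_preserved(self):
        assert rates.hetnoe(-10.0, 100.0).noe_ratio == -0.1

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            rates.hetnoe(10.0, 0.0)


class TestR2eff:
    @pytest.mark.parametrize("i_rel,expected", [
        (1.0, 0.0),
        (math.exp(-1.0), 25.0),          # I/I0 = e^-1, T = 40 ms
        (0.5, math.log(2) / 0.04),       # ln2 / 0.04 = 17.33
    ])
    def test_log_ratio(self, i_rel, expected):
        assert rates.r2eff_from_intensities(i_rel * 80.0, 80.0, 0.04) == \
            pytest.approx(expected, rel=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            rates.r2eff_from_intensities(-1.0, 80.0, 0.04)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_strictly_decreasing_in_intensity(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert rates.r2eff_from_intensities(hi, 1.0, 0.04) < \
            rates.r2eff_from_intensities(lo, 1.0, 0.04)


class TestDeltaR2eff:
    def test_flat_profile_zero(self):
        assert rates.delta_r2eff([25, 750], [20.0, 20.0]) == 0.0

    def test_low_minus_high(self):
        assert rates.delta_r2eff([25, 750], [30.0, 22.0]) == pytest.approx(8.0)

    def test_order_invariance(self):
        assert rates.delta_r2eff([750, 100, 25], [22.0, 25.0, 30.0]) == \
            rates.delta_r2eff([25, 100, 750], [30.0, 25.0, 22.0])


class TestR1R2Product:
    def test_product_and_error(self):
        prod, err = rates.r1r2_product(1.5, 12.0, 0.1, 0.5)
        assert prod == pytest.approx(18.0)
        assert err == pytest.approx(math.hypot(12 * 0.1, 1.5 * 0.5), rel=1e-9)

    def test_zero_rate(self):
        assert rates.r1r2_product(0.0, 12.0)[0] == 0.0


class TestTract:
    def test_equal_rates_flagged(self):
        res = rates.tract_tc(12.0, 12.0, 16.4)
        assert "unphysical_eta" in res["flags"]
        assert math.isnan(res["tau_c"])

    def test_forward_inverse_round_trip(self):
        eta = rates.tract_eta_xy(8.2e-9, 16.4)
        res = rates.tract_tc(10.0, 10.0 + 2 * eta, 16.4)
        assert res["tau_c"] == pytest.approx(8.2e-9, rel=1e-9)

    def test_slow_tumbling_linearity(self):
        # in the slow-tumbling limit eta ~ J(0) ~ tau_c, so doubling the
        # rate difference roughly doubles tau_c
        eta = rates.tract_eta_xy(20e-9, 16.4)
        tc1 = rates.tract_tc(10.0, 10.0 + 2 * eta, 16.4)["tau_c"]
        tc2 = rates.tract_tc(10.0, 10.0 + 4 * eta, 16.4)["tau_c"]
        assert tc2 / tc1 == pytest.approx(2.0, rel=0.02)

    def test_magnitude_plausible_for_small_domain(self):
        # a ~12 kDa domain at 8.2 ns / 16.4 T should give eta_xy ~ 5-20 s^-1
        eta = rates.tract_eta_xy(8.2e-9, 16.4)
        assert 5.0 < eta < 20.0


class TestMonteCarloErrors:
    @staticmethod
    def _fit(y):
        t = np.linspace(0.1, 1.0, 6)
        slope, icpt = np.polyfit(t, np.log(np.maximum(y, 1e-12)), 1)
        return [-slope]

    def test_zero_noise_zero_sigma(self):
        t = np.linspace(0.1, 1.0, 6)
        model = 100 * np.exp(-2 * t)
        sig = rates.montecarlo_errors(self._fit, model, 0.0, n_draws=50, seed=0)
        assert sig[0] == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducible(self):
        t = np.linspace(0.1, 1.0, 6)
        model = 100 * np.exp(-2 * t)
        a = rates.montecarlo_errors(self._fit, model, 1.0, n_draws=100, seed=7)
        b = rates.montecarlo_errors(self._fit, model, 1.0, n_draws=100, seed=7)
        assert a[0] == b[0]

    def test_linear_noise_scaling(self):
        t = np.linspace(0.1, 1.0, 6)
        model = 100 * np.exp(-2 * t)
        s1 = rates.montecarlo_errors(self._fit, model, 0.5, n_draws=400, seed=3)
        s2 = rates.montecarlo_errors(self._fit, model, 1.0, n_draws=400, seed=3)
        assert s2[0] / s1[0] == pytest.approx(2.0, rel=0.2)

    def test_minimum_draw_count(self):
        with pytest.raises(ValueError):
            rates.montecarlo_errors(self._fit, np.ones(6), 1.0, n_draws=10)
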