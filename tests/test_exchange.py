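"""Two-state exchange: CPMG propagators, closed-form cross-checks, lineshapes."""
import math

import numpy as np
import pytest

from nmrdyn import constants as K
from nmrdyn import exchange as ex
from nmrdyn import synth

T_RELAX = 0.040


def sq_r2eff(nu, p_b, k_ex, dw, r2_0):
    n = int(round(2 * T_RELAX * nu))
    i_rel = ex._sq_intensity(dw, p_b * k_ex, (1 - p_b) * k_ex, r2_0, r2_0, T_RELAX, n)
    return -math.log(i_rel) / T_RELAX


class TestSQPropagator:
    def test_no_minor_state_flat(self):
        model = ex.TwoStateExchangeModel(p_b=1e-9, k_ex=1000.0, dw_x_ppm={"A": 2.0},
                                         r2_0={("A", 16.4): 8.0})
        prof = ex.simulate_cpmg_sq(model, ex.CPMGExperiment(b0=16.4))
        np.testing.assert_allclose(prof["R2eff"], 8.0, atol=1e-6)

    def test_zero_shift_difference_flat(self):
        model = ex.TwoStateExchangeModel(p_b=0.15, k_ex=1000.0, dw_x_ppm={"A": 0.0},
                                         r2_0={("A", 16.4): 8.0})
        prof = ex.simulate_cpmg_sq(model, ex.CPMGExperiment(b0=16.4))
        np.testing.assert_allclose(prof["R2eff"], 8.0, atol=1e-8)

    def test_matches_luz_meiboom_in_fast_exchange(self):
        dw = 0.5e-6 * abs(K.GAMMA_N) * 16.4
        for nu in (25, 100, 500, 1500):
            got = sq_r2eff(nu, 0.1, 1e4, dw, 8.0)
            want = ex.luz_meiboom(nu, 0.1, 1e4, dw, 8.0)
            assert got == pytest.approx(want, rel=0.01)

    def test_matches_carver_richards_over_grid(self):
        # 20 (p_B, k_ex) combinations; the closed form is the asymptotic
        # dominant-eigenvalue result, so compare at high refocusing rates
        # where its amplitude-factor neglect is valid
        dw = 2.0e-6 * abs(K.GAMMA_N) * 16.4
        for p_b in (0.05, 0.10, 0.152, 0.20):
            for k_ex in (840.0, 1500.0, 2400.0, 5000.0, 8000.0):
                for nu in (750, 1500):
                    got = sq_r2eff(nu, p_b, k_ex, dw, 8.0)
                    want = ex.carver_richards(nu, p_b, k_ex, dw, 8.0, 8.0)
                    assert got == pytest.approx(want, rel=0.01)

    def test_high_frequency_limit_population_average(self):
        # R2eff(nu -> inf) approaches the population-averaged intrinsic rate
        dw = 2.0e-6 * abs(K.GAMMA_N) * 16.4
        got = sq_r2eff(8000, 0.15, 2000.0, dw, 8.0)
        assert got == pytest.approx(8.0, rel=0.02)

    def test_dispersion_non_increasing(self):
        dw = 2.0e-6 * abs(K.GAMMA_N) * 16.4
        vals = [sq_r2eff(nu, 0.15, 2400.0, dw, 8.0)
                for nu in (25, 50, 100, 250, 500, 1000, 1500)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


class TestMQPropagator:
    def test_reduces_to_sq_without_proton_shift(self):
        dwc = 1.5e-6 * K.GAMMA_C * 16.4
        for nu in (25, 125, 250, 750):
            n = int(round(2 * T_RELAX * nu))
            isq = ex._sq_intensity(dwc, 0.166 * 840, 0.834 * 840, 10, 10, T_RELAX, n)
            imq = ex._mq_intensity(0.0, dwc, 0.166 * 840, 0.834 * 840, 10, 10,
                                   T_RELAX, n)
            assert imq == pytest.approx(isq, rel=1e-10)

    def test_no_minor_state_flat(self):
        model = ex.TwoStateExchangeModel(p_b=1e-9, k_ex=840.0,
                                         dw_x_ppm={"A": 1.5}, dw_h_ppm={"A": 0.1},
                                         r2_0={("A", 16.4): 10.0})
        prof = ex.simulate_cpmg_mq(model, ex.CPMGExperiment(
            coherence="MQ_13C1H", b0=16.4, nu_cpmg=(25, 125, 250, 750)))
        np.testing.assert_allclose(prof["R2eff"], 10.0, atol=1e-6)

    def test_reported_methyl_regime_disperses(self):
        # 16.6% minor state on a 1.19 ms timescale gives a clearly non-flat
        # profile for a typical methyl shift difference
        model = ex.TwoStateExchangeModel(
            p_b=0.166, k_ex=1000.0 / 1.19, dw_x_ppm={"A": 1.5},
            dw_h_ppm={"A": 0.1}, r2_0={("A", 16.4): 10.0})
        prof = ex.simulate_cpmg_mq(model, ex.CPMGExperiment(
            coherence="MQ_13C1H", b0=16.4, nu_cpmg=(25, 50, 125, 250, 500, 750)))
        nu = prof["nu_cpmg_Hz"].to_numpy()
        r2 = prof["R2eff"].to_numpy()
        assert r2[np.argmin(nu)] - r2[np.argmax(nu)] > 5.0


class TestGlobalDispersionFit:
    def test_noiseless_self_consistency(self):
        dw = {1: 1.5, 2: 2.5, 3: 3.0}
        model = ex.TwoStateExchangeModel(p_b=0.15, k_ex=2400.0, dw_x_ppm=dw,
                                         r2_0={(p, b): 10.0 for p in dw
                                               for b in (16.4, 21.1)})
        data = synth.gen_dispersion(model, "SQ_15N", (16.4, 21.1),
                                    (25, 50, 100, 250, 500, 1000, 1500), noise=0.0)
        fit = ex.fit_dispersion_global(data, "SQ_15N")
        assert fit.k_ex == pytest.approx(2400.0, rel=1e-4)
        assert fit.p_b == pytest.approx(0.15, rel=1e-4)
        for p in dw:
            assert fit.dw_x_ppm[p] == pytest.approx(dw[p], rel=1e-3)

    def test_flat_probe_does_not_perturb_global_parameters(self):
        dw = {1: 2.0, 2: 2.5, 3: 0.0}  # probe 3 is flat
        model = ex.TwoStateExchangeModel(p_b=0.15, k_ex=2400.0, dw_x_ppm=dw,
                                         r2_0={(p, b): 10.0 for p in dw
                                               for b in (16.4, 21.1)})
        data = synth.gen_dispersion(model, "SQ_15N", (16.4, 21.1),
                                    (25, 50, 100, 250, 500, 1000, 1500), noise=0.0)
        fit = ex.fit_dispersion_global(data, "SQ_15N")
        assert fit.k_ex == pytest.approx(2400.0, rel=0.01)
        assert fit.dw_x_ppm[3] == pytest.approx(0.0, abs=0.05)

    def test_all_flat_input_rejected(self):
        dw = {1: 0.0, 2: 0.0}
        model = ex.TwoStateExchangeModel(p_b=0.15, k_ex=2400.0, dw_x_ppm=dw,
                                         r2_0={(p, 16.4): 10.0 for p in dw})
        data = synth.gen_dispersion(model, "SQ_15N", (16.4,),
                                    (25, 100, 500, 1500), noise=0.001, seed=0)
        with pytest.raises(ex.DegenerateFitError):
            ex.fit_dispersion_global(data, "SQ_15N")


class TestFreeLigand:
    def test_no_ligand(self):
        assert ex.equilibrium_free_ligand(1e-4, 0.0, 1e-6) == (0.0, 0.0)

    def test_weak_binding_limit(self):
        l_free, bound = ex.equilibrium_free_ligand(1e-4, 5e-5, 10.0)
        assert l_free == pytest.approx(5e-5, rel=1e-4)
        assert bound < 1e-5

    def test_stoichiometric_limit(self):
        # P = 100 uM, L = 50 uM, K_D = 1 nM: essentially all ligand bound
        l_free, bound = ex.equilibrium_free_ligand(100e-6, 50e-6, 1e-9)
        assert l_free < 1e-8
        assert bound * 100e-6 == pytest.approx(50e-6, rel=1e-3)

    def test_mass_conservation_property(self):
        for lt in (1e-6, 1e-4, 1e-2):
            l_free, bound = ex.equilibrium_free_ligand(250e-6, lt, 3.18e-6)
            assert l_free + bound * 250e-6 == pytest.approx(lt, rel=1e-9)


class TestLineshapes:
    grid = np.linspace(-150, 270, 2048)

    def test_fast_exchange_single_population_weighted_peak(self):
        binding = ex.BindingModel(1e-4, 1e6, 0.0, 120.0, 20.0, 20.0)
        lt = 1e-4  # bound fraction from the equilibrium
        spec = ex.simulate_lineshape_titration(binding, 1e-4, [lt], self.grid)[0]
        _, fb = ex.equilibrium_free_ligand(1e-4, lt, binding.k_d)
        expected_peak = fb * 120.0
        peak_pos = self.grid[np.argmax(spec)]
        assert peak_pos == pytest.approx(expected_peak, abs=1.0)

    def test_slow_exchange_two_peaks_with_population_areas(self):
        binding = ex.BindingModel(1e-6, 1e-2, 0.0, 120.0, 20.0, 20.0)
        lt = 120e-6
        spec = ex.simulate_lineshape_titration(binding, 250e-6, [lt], self.grid)[0]
        _, fb = ex.equilibrium_free_ligand(250e-6, lt, binding.k_d)
        mid = np.searchsorted(self.grid, 60.0)
        area_free = np.trapezoid(spec[:mid], self.grid[:mid])
        area_bound = np.trapezoid(spec[mid:], self.grid[mid:])
        assert area_bound / (area_free + area_bound) == pytest.approx(fb, abs=0.01)

    def test_integral_conserved_across_titration(self):
        binding = ex.BindingModel(3.18e-6, 48.5, 0.0, 120.0, 20.0, 20.0)
        l_totals = np.linspace(0, 500e-6, 6)
        wide = np.linspace(-2000, 2120, 16384)  # capture the Lorentzian tails
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            specs = ex.simulate_lineshape_titration(binding, 250e-6, l_totals, wide)
        integrals = [np.trapezoid(s, wide) for s in specs]
        assert max(integrals) / min(integrals) - 1 < 1e-3

    def test_noiseless_titration_fit_identity(self):
        binding = ex.BindingModel(3.18e-6, 48.5, 0.0, 120.0, 20.0, 20.0)
        grid = np.linspace(-150, 270, 512)
        l_totals = np.linspace(0, 500e-6, 8)
        specs = ex.simulate_lineshape_titration(binding, 250e-6, l_totals, grid)
        init = ex.BindingModel(10e-6, 100.0, 0.0, 120.0, 20.0, 20.0)
        fit = ex.fit_lineshape_titration(specs, 250e-6, l_totals, grid, init,
                                         multistart=False)
        assert fit.k_d == pytest.approx(3.18e-6, rel=1e-3)
        assert fit.k_off == pytest.approx(48.5, rel=1e-3)

    def test_metal_regime_recovery(self):
        binding = ex.BindingModel(4.1e-3, 84.3, 0.0, 120.0, 20.0, 20.0)
        grid = np.linspace(-150, 270, 512)
        l_totals = np.linspace(0, 40e-3, 8)
        specs, _ = synth.gen_lineshape(binding, 250e-6, l_totals, grid,
                                       noise=0.01, seed=14)
        init = ex.BindingModel(1e-3, 150.0, 0.0, 120.0, 20.0, 20.0)
        fit = ex.fit_lineshape_titration(specs, 250e-6, l_totals, grid, init)
        assert fit.k_d == pytest.approx(4.1e-3, rel=0.15)
        assert fit.k_off == pytest.approx(84.3, rel=0.15)


class TestModelInvariants:
    def test_tau_ex_kex_relation(self):
        model = ex.TwoStateExchangeModel(p_b=0.1, k_ex=2500.0)
        assert model.tau_ex_ms * model.k_ex == pytest.approx(1000.0)

    def test_population_bounds_enforced(self):
        with pytest.raises(ValueError):
            ex.TwoStateExchangeModel(p_b=0.6, k_ex=1000.0)
        with pytest.raises(ValueError):
            ex.TwoStateExchangeModel(p_b=0.1, k_ex=-1.0)
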