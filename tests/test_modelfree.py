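"""Lipari-Szabo model-free forward model, filtering and fitting."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrdyn import constants as K
from nmrdyn import modelfree as mf
from nmrdyn import synth


def rigid_rotor_rates(tau_c, b0):
    """Independent closed-form (R1, R2, NOE) for S2 = 1 isotropic tumbling.

    Written out directly from the dipolar + CSA expressions with a single
    Lorentzian spectral density; kept separate from the package routine on
    purpose.
    """
    wh = K.GAMMA_H * b0
    wn = abs(K.GAMMA_N) * b0
    d = K.MU0_OVER_4PI * K.GAMMA_H * abs(K.GAMMA_N) * K.HBAR / K.R_NH**3
    j = lambda w: 0.4 * tau_c / (1 + (w * tau_c) ** 2)
    c2 = (wn * K.CSA_N) ** 2 / 3
    r1 = d * d / 4 * (j(wh - wn) + 3 * j(wn) + 6 * j(wh + wn)) + c2 * j(wn)
    r2 = d * d / 8 * (4 * j(0) + j(wh - wn) + 3 * j(wn) + 6 * j(wh) + 6 * j(wh + wn)) \
        + c2 / 6 * (4 * j(0) + 3 * j(wn))
    noe = 1 + (K.GAMMA_H / K.GAMMA_N) * (d * d / 4) * (6 * j(wh + wn) - j(wh - wn)) / r1
    return r1, r2, noe


class TestPredictRates:
    def test_rigid_limit_matches_closed_form(self):
        params = mf.ModelFreeParams(S2=1.0)
        tensor = mf.DiffusionTensor(tau_c=8.2e-9)
        got = mf.predict_rates(params, tensor, 16.4)
        want = rigid_rotor_rates(8.2e-9, 16.4)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_tau_e_zero_limit_scales_rigid_spectrum(self):
        # with tau_e -> 0 the internal term carries no spectral weight:
        # every J(omega) is S2 times the rigid value
        s2 = 0.85
        tensor = mf.DiffusionTensor(tau_c=8.2e-9)
        taus, weights = tensor.branches(None)
        j_rigid = mf._jw(np.array([0.0, 1e8]), 1.0, 0.0, taus, weights)
        j_scaled = mf._jw(np.array([0.0, 1e8]), s2, 0.0, taus, weights)
        np.testing.assert_allclose(j_scaled, s2 * j_rigid, rtol=1e-12)

    def test_degenerate_axial_tensor_equals_isotropic(self):
        params = mf.ModelFreeParams(S2=0.9, tau_e=40e-12)
        iso = mf.DiffusionTensor(mode="isotropic", tau_c=8e-9)
        ax = mf.DiffusionTensor(mode="axial", tau_c=8e-9, d_ratio=1.0,
                                axis=(0.3, 1.1))
        for vec in ([1, 0, 0], [0.4, 0.5, 0.77]):
            v = np.asarray(vec) / np.linalg.norm(vec)
            np.testing.assert_allclose(
                mf.predict_rates(params, ax, 16.4, v),
                mf.predict_rates(params, iso, 16.4), rtol=1e-10)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0.1, 1.0), st.floats(1e-12, 2e-9), st.floats(1e-9, 40e-9))
    def test_hetnoe_physical_bounds(self, s2, tau_e, tau_c):
        params = mf.ModelFreeParams(S2=s2, tau_e=tau_e)
        tensor = mf.DiffusionTensor(tau_c=tau_c)
        _, _, noe = mf.predict_rates(params, tensor, 16.4)
        assert -4.0 < noe < 1.0

    def test_rex_scales_with_field_squared(self):
        params = mf.ModelFreeParams(S2=0.9, Rex=5.0)
        tensor = mf.DiffusionTensor(tau_c=8e-9)
        base = mf.ModelFreeParams(S2=0.9)
        for b0 in (16.4, 21.1):
            r2_with = mf.predict_rates(params, tensor, b0)[1]
            r2_without = mf.predict_rates(base, tensor, b0)[1]
            assert r2_with - r2_without == pytest.approx(5.0 * (b0 / 16.4) ** 2)


class TestFilterProbes:
    def make(self, ratios):
        return pd.DataFrame({"probe": range(len(ratios)), "R1": [1.0] * len(ratios),
                             "R2": ratios})

    def test_above_threshold_excluded(self):
        retained, excluded = mf.filter_probes(self.make([31.0]))
        assert len(excluded) == 1 and len(retained) == 0

    def test_boundary_retained(self):
        retained, excluded = mf.filter_probes(self.make([30.0]))
        assert len(retained) == 1 and len(excluded) == 0

    def test_empty_input(self):
        retained, excluded = mf.filter_probes(self.make([]))
        assert retained.empty and excluded.empty


class TestEstimateTc:
    def test_round_trip_from_forward_model(self):
        s2 = {i: 0.9 for i in range(1, 11)}
        tensor = mf.DiffusionTensor(tau_c=8.2e-9)
        data = synth.gen_relaxation_triples(s2, tensor, fields=(16.4,), noise=0.0)
        tc = mf.estimate_tc(data, 16.4)
        assert tc == pytest.approx(8.2e-9, rel=0.10)

    def test_consistent_across_fields(self):
        s2 = {i: 0.9 for i in range(1, 11)}
        tensor = mf.DiffusionTensor(tau_c=8.2e-9)
        ests = []
        for b0 in (16.4, 21.1):
            data = synth.gen_relaxation_triples(s2, tensor, fields=(b0,), noise=0.0)
            ests.append(mf.estimate_tc(data, b0))
        assert abs(ests[0] - ests[1]) / ests[0] < 0.05

    def test_too_few_probes(self):
        s2 = {1: 0.9}
        tensor = mf.DiffusionTensor(tau_c=8e-9)
        data = synth.gen_relaxation_triples(s2, tensor, noise=0.0)
        with pytest.raises(ValueError):
            mf.estimate_tc(data, 16.4)


class TestFitModelfree:
    def test_noiseless_rigid_selects_simplest_model(self):
        s2 = {i: 0.82 + 0.01 * i for i in range(1, 9)}
        tensor = mf.DiffusionTensor(tau_c=8.2e-9)
        data = synth.gen_relaxation_triples(s2, tensor, fields=(16.4,), noise=0.0)
        fit_tensor, params = mf.fit_modelfree(data)
        assert fit_tensor.tau_c == pytest.approx(8.2e-9, rel=1e-3)
        for p in params:
            assert p.model_id == "M1"
            assert p.S2 == pytest.approx(s2[p.probe], abs=1e-4)

    def test_injected_rex_detected_at_two_fields(self):
        s2 = {i: 0.9 for i in range(1, 16)}
        rex = {i: 5.0 for i in range(1, 8)}  # first half carries exchange
        tensor = mf.DiffusionTensor(tau_c=8.2e-9)
        data = synth.gen_relaxation_triples(s2, tensor, fields=(16.4, 21.1),
                                            rex=rex, noise=0.01, seed=5)
        _, params = mf.fit_modelfree(data)
        hits = sum(1 for p in params if p.probe in rex and p.model_id in ("M3", "M4"))
        assert hits / len(rex) > 0.9

    def test_axial_fit_of_isotropic_truth(self):
        rng = np.random.default_rng(2)
        s2 = {i: 0.9 for i in range(1, 9)}
        vectors = {}
        for i in s2:
            v = rng.normal(size=3)
            vectors[i] = v / np.linalg.norm(v)
        tensor = mf.DiffusionTensor(tau_c=8e-9)
        data = synth.gen_relaxation_triples(s2, tensor, fields=(16.4,),
                                            vectors=vectors, noise=0.0)
        fit_tensor, _ = mf.fit_modelfree(data, vectors=vectors, mode="axial",
                                         models=("M1",))
        assert fit_tensor.d_ratio == pytest.approx(1.0, abs=0.05)
        assert fit_tensor.tau_c == pytest.approx(8e-9, rel=0.02)
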