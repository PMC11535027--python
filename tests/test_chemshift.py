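"""Chemical-shift analytics: CSPs, secondary shifts, rotamers, NOE networks."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrdyn import chemshift as cs


def shift_table(probes, h, x, x_col="delta_N"):
    return pd.DataFrame({"probe": probes, "delta_H": h, x_col: x})


class TestCSP:
    @pytest.mark.parametrize("dh,dn,expected", [
        (0.1, 0.0, 0.1),          # pure 1H component
        (0.0, 1.0, 0.2),          # 15N scaled by 1/5
        (0.03, 0.20, 0.05),       # sqrt(0.0009 + 0.0016)
    ])
    def test_amide_weighting(self, dh, dn, expected):
        ref = shift_table(["A"], [8.0], [120.0])
        per = shift_table(["A"], [8.0 + dh], [120.0 + dn])
        out = cs.compute_csp_amide(ref, per)
        assert out["csp"].iloc[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("dh,dc,expected", [
        (0.0, 0.4, 0.1),          # 13C scaled by 1/4
        (0.0, 0.0, 0.0),
        (0.06, 0.32, 0.1),        # sqrt(0.0036 + 0.0064)
    ])
    def test_methyl_weighting(self, dh, dc, expected):
        ref = shift_table(["A"], [0.8], [12.0], "delta_C")
        per = shift_table(["A"], [0.8 + dh], [12.0 + dc], "delta_C")
        out = cs.compute_csp_methyl(ref, per)
        assert out["csp"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_table_order(self):
        ref = shift_table(list("ABC"), [8.0, 8.2, 7.9], [118, 120, 122])
        per = shift_table(list("ABC"), [8.1, 8.0, 7.9], [119, 121, 122])
        fwd = cs.compute_csp_amide(ref, per)["csp"]
        rev = cs.compute_csp_amide(per, ref)["csp"]
        np.testing.assert_allclose(fwd, rev)

    def test_no_overlap_raises(self):
        ref = shift_table(["A"], [8.0], [120.0])
        per = shift_table(["B"], [8.0], [120.0])
        with pytest.raises(cs.EmptyOverlapError):
            cs.compute_csp_amide(ref, per)


class TestSignificance:
    def test_single_outlier_flagged_1sd(self):
        df = pd.DataFrame({"probe": list("ABCD"), "csp": [0, 0, 0, 1.0]})
        out = cs.flag_significant(df, "1SD")
        assert list(out["significant"]) == ["none", "none", "none", "1SD"]

    def test_all_equal_none_flagged(self):
        df = pd.DataFrame({"probe": list("ABCD"), "csp": [0.1] * 4})
        with pytest.warns(UserWarning, match="zero spread"):
            out = cs.flag_significant(df, "1SD")
        assert (out["significant"] == "none").all()

    def test_corrected_to_zero_iterates(self):
        df = pd.DataFrame({"probe": range(10), "csp": [0.01] * 9 + [0.5]})
        out = cs.flag_significant(df, "2SD", corrected_to_zero=True)
        assert list(out["significant"])[-1] == "2SD"
        assert (out["significant"][:9] == "none").all()


class TestSecondaryShifts:
    def make(self, residues, ca, cb):
        obs = pd.DataFrame({"residue": residues, "delta_CA": ca, "delta_CB": cb})
        rc = pd.DataFrame({"residue": residues,
                           "delta_CA": [50.0] * len(residues),
                           "delta_CB": [30.0] * len(residues)})
        return obs, rc

    def test_zero_raw_gives_zero_smoothed(self):
        obs, rc = self.make([1, 2, 3], [50, 50, 50], [30, 30, 30])
        out = cs.secondary_shifts(obs, rc)
        np.testing.assert_allclose(out["smoothed"], 0.0)

    def test_121_weighting(self):
        # raw = {0, 4, 0}: smoothed(2) = (0 + 2*4 + 0)/4 = 2
        obs, rc = self.make([1, 2, 3], [50, 54, 50], [30, 30, 30])
        out = cs.secondary_shifts(obs, rc)
        assert out.loc[out["residue"] == 2, "smoothed"].iloc[0] == pytest.approx(2.0)

    def test_terminal_weight_renormalised(self):
        # raw = {4, 4}: smoothed(1) = (2*4 + 4)/3 = 4
        obs, rc = self.make([1, 2], [54, 54], [30, 30])
        out = cs.secondary_shifts(obs, rc)
        assert out.loc[out["residue"] == 1, "smoothed"].iloc[0] == pytest.approx(4.0)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=15))
    def test_smoothing_never_amplifies_extremes(self, raw):
        residues = list(range(1, len(raw) + 1))
        obs, rc = self.make(residues, [50 + r for r in raw], [30.0] * len(raw))
        out = cs.secondary_shifts(obs, rc)
        assert out["smoothed"].abs().max() <= abs(max(raw, key=abs)) + 1e-9


class TestRotamers:
    @pytest.mark.parametrize("label,shift,p,klass", [
        ("Met-e", 15.9, 0.0, "gauche_minus"),   # calibration intercept
        ("Ile-d1", 14.8, 1.0, "trans"),          # 9.3 + 5.5
        ("Ile-d1", 12.05, 0.5, "mixed"),         # calibration midpoint
    ])
    def test_linear_calibration(self, label, shift, p, klass):
        rec = cs.rotamer_population("X", shift, atom_label=label)
        assert rec["p_trans"] == pytest.approx(p, abs=1e-12)
        assert rec["rotamer_class"] == klass

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            rec = cs.rotamer_population("X", 8.0, atom_label="Ile-d1")
        assert rec["p_trans"] == 0.0

    def test_wrong_probe_class_rejected(self):
        with pytest.raises(TypeError):
            cs.rotamer_population("X", 20.0, atom_label="Ala-b")

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 1))
    def test_inverse_map_identity(self, p):
        intercept, slope = cs.ROTAMER_CALIBRATIONS["Ile-d1"]
        rec = cs.rotamer_population("X", intercept + slope * p, atom_label="Ile-d1")
        assert rec["p_trans"] == pytest.approx(p, abs=1e-12)

    def test_rotamer_delta_direction(self):
        apo = pd.DataFrame({"probe": ["I150", "I164"], "p_trans": [0.8, 0.5]})
        holo = pd.DataFrame({"probe": ["I150", "I166"], "p_trans": [0.6, 0.9]})
        out = cs.rotamer_delta(holo, apo)
        assert len(out) == 1
        assert out["delta_p_trans"].iloc[0] == pytest.approx(-0.2)
        assert out["direction"].iloc[0] == "toward_gauche_minus"
        assert out.attrs["apo_only"] == ["I164"]

    def test_rotamer_delta_identity(self):
        t = pd.DataFrame({"probe": ["A", "B"], "p_trans": [0.3, 0.9]})
        out = cs.rotamer_delta(t, t)
        assert (out["delta_p_trans"] == 0).all()


class TestNOENetwork:
    def test_reciprocal_peaks_collapse(self):
        peaks = pd.DataFrame({"probe_a": ["A", "B"], "probe_b": ["B", "A"],
                              "intensity": [1.0, 3.0]})
        g = cs.build_noe_network(peaks)
        assert g.number_of_edges() == 1
        assert g.edges["A", "B"]["count"] == 2
        assert g.edges["A", "B"]["mean_intensity"] == pytest.approx(2.0)

    def test_self_pairs_dropped(self):
        peaks = pd.DataFrame({"probe_a": ["A"], "probe_b": ["A"]})
        with pytest.warns(UserWarning, match="self-pair"):
            g = cs.build_noe_network(peaks)
        assert g.number_of_edges() == 0

    def test_empty_list_gives_empty_network(self):
        g = cs.build_noe_network(pd.DataFrame({"probe_a": [], "probe_b": []}))
        assert g.number_of_nodes() == 0

    def test_diff_set_algebra(self):
        a = cs.build_noe_network(pd.DataFrame(
            {"probe_a": ["A", "B"], "probe_b": ["B", "C"]}))
        b = cs.build_noe_network(pd.DataFrame(
            {"probe_a": ["B", "C"], "probe_b": ["C", "D"]}))
        diff = cs.diff_noe_networks(a, b)
        assert diff["gained"] == {frozenset({"C", "D"})}
        assert diff["lost"] == {frozenset({"A", "B"})}
        assert diff["retained"] == {frozenset({"B", "C"})}

    def test_self_diff_retains_everything(self):
        a = cs.build_noe_network(pd.DataFrame(
            {"probe_a": ["A", "B"], "probe_b": ["B", "C"]}))
        diff = cs.diff_noe_networks(a, a)
        assert diff["gained"] == set() and diff["lost"] == set()
        assert diff["retained"] == {frozenset(e) for e in a.edges}
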