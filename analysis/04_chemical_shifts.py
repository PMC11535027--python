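#!/usr/bin/env python
"""Chemical-shift analytics: CSPs, secondary shifts, rotamers, NOE networks.

Runs the full shift-based toolchain on synthetic apo/holo shift tables that
emulate peptide binding at the recognition groove: weighted CSPs with 2SD
corrected-to-zero significance flagging, 1-2-1-smoothed Ca/Cb secondary
shifts, Ile/Met rotamer populations with apo->holo deltas (including the
~20% gauche(-) shift seen near the active site), and the gained/lost/
retained NOE edge sets.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nmrdyn import chemshift as cs
from nmrdyn import tables

SEED = 20240602
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    # --- amide CSPs: binding-groove residues perturbed, rest jitter only
    residues = list(range(349, 459))
    groove = set(rng.choice(residues, 12, replace=False))
    ref = pd.DataFrame({"probe": residues,
                        "delta_H": 8.0 + rng.normal(0, 0.3, len(residues)),
                        "delta_N": 120.0 + rng.normal(0, 3, len(residues))})
    per = ref.copy()
    jitter_h = rng.normal(0, 0.003, len(residues))
    jitter_n = rng.normal(0, 0.02, len(residues))
    per["delta_H"] = per["delta_H"] + jitter_h
    per["delta_N"] = per["delta_N"] + jitter_n
    mask = per["probe"].isin(groove)
    per.loc[mask, "delta_H"] += rng.uniform(0.05, 0.25, mask.sum())
    per.loc[mask, "delta_N"] += rng.uniform(0.3, 1.5, mask.sum())
    csps = cs.flag_significant(cs.compute_csp_amide(ref, per), "2SD",
                               corrected_to_zero=True)
    hits = set(csps.loc[csps["significant"] != "none", "probe"])
    print(f"CSP mapping: {len(hits & groove)}/{len(groove)} perturbed residues "
          f"recovered at 2SD (corrected to zero); "
          f"{len(hits - groove)} background residues co-flagged")
    tables.write_results(csps, OUT / "csp_amide.csv")

    # --- secondary shifts: a short helix on a coil background
    ss_res = list(range(400, 421))
    raw = np.zeros(len(ss_res))
    raw[5:12] = 3.0  # helical stretch
    obs = pd.DataFrame({"residue": ss_res, "delta_CA": 56.0 + raw / 2,
                        "delta_CB": 32.0 - raw / 2})
    rc = pd.DataFrame({"residue": ss_res, "delta_CA": 56.0, "delta_CB": 32.0})
    sec = cs.secondary_shifts(obs, rc)
    helical = sec.loc[(sec["residue"] >= 405) & (sec["residue"] <= 411), "smoothed"]
    print(f"secondary shifts: helix segment mean {helical.mean():.2f} ppm "
          f"(positive = helical)")
    tables.write_results(sec, OUT / "secondary_shifts.csv")

    # --- rotamers: apo/holo Ile-d1 populations; two probes shift ~20% toward
    # gauche(-) on activation
    apo_p = {164: 0.50, 166: 0.55, 362: 0.80, 397: 0.85}
    holo_p = {164: 0.30, 166: 0.35, 362: 0.60, 397: 0.85}
    icpt, slope = cs.ROTAMER_CALIBRATIONS["Ile-d1"]
    apo = pd.DataFrame([cs.rotamer_population(r, icpt + slope * p, "Ile-d1")
                        for r, p in apo_p.items()])
    holo = pd.DataFrame([cs.rotamer_population(r, icpt + slope * p, "Ile-d1")
                         for r, p in holo_p.items()])
    delta = cs.rotamer_delta(holo, apo)
    toward_g = delta.loc[delta["direction"] == "toward_gauche_minus", "probe"]
    print(f"rotamer deltas: {len(toward_g)} probes move toward gauche(-) "
          f"on activation: {sorted(toward_g)}")
    tables.write_results(delta, OUT / "rotamer_delta.csv")

    # --- NOE networks: detachment of one structural element on activation
    apo_edges = pd.DataFrame({
        "probe_a": ["I373", "I373", "V364", "L367", "I397"],
        "probe_b": ["V364", "L367", "L367", "I397", "M366"]})
    holo_edges = pd.DataFrame({
        "probe_a": ["V364", "L367", "I397", "I150"],
        "probe_b": ["L367", "I397", "M366", "I155"]})
    diff = cs.diff_noe_networks(cs.build_noe_network(apo_edges),
                                cs.build_noe_network(holo_edges))
    print(f"NOE diff: {len(diff['lost'])} lost, {len(diff['gained'])} gained, "
          f"{len(diff['retained'])} retained")
    (OUT / "noe_diff.json").write_text(json.dumps(
        {k: [sorted(e) for e in v] for k, v in diff.items()}, indent=2))
    print(f"wrote tables under {OUT}")


if __name__ == "__main__":
    main()
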