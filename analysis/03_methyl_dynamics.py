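#!/usr/bin/env python
"""Methyl side-chain dynamics: SQ/TQ cross-correlated relaxation and MQ CPMG.

Fast (ps-ns) motion: fits the SQ/TQ intensity-ratio build-up (13 delays,
2-45 ms) for a 20-methyl core cohort generated at S2axis*tau_c = 4.3 ns.
Slow (us-ms) motion: global two-field MQ dispersion fit at the measured
methyl exchange condition (16.6% minor state, 1.19 ms).
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nmrdyn import ccr, exchange, synth, tables

SEED = 20240601
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    # --- ps-ns: cross-correlated relaxation cohort
    delays = np.array(synth.SCENARIOS["methyl_ccr"]["delays_ms"]) * 1e-3
    cohort = {i: 4.3 for i in range(1, 21)}
    data = synth.gen_ccr(cohort, delays, delta=2.0, noise=0.02, seed=SEED)
    rows = []
    for probe, grp in data.groupby("probe"):
        fit = ccr.fit_ccr(grp["T_s"].to_numpy(), grp["ratio"].to_numpy(),
                          probe=probe)
        rows.append({"probe": probe, "eta": fit.eta, "delta": fit.delta,
                     "s2_tauc_ns": fit.s2_tauc_ns})
    df = pd.DataFrame(rows)
    mean_s2tc = df["s2_tauc_ns"].mean()
    print(f"core cohort mean S2axis*tau_c = {mean_s2tc:.2f} ns (generated 4.3)")
    # D2O-viscosity-corrected tumbling time consistent with the backbone value
    tc_d2o = ccr.d2o_tc_correction(8.2e-9)
    print(f"D2O-corrected tau_c used for S2axis extraction: {tc_d2o*1e9:.2f} ns")
    tables.write_results(df, OUT / "methyl_ccr.csv")

    # --- us-ms: methyl MQ dispersion
    rng = np.random.default_rng(SEED + 5)
    dw = {i: float(rng.uniform(0.5, 2.0)) for i in range(1, 9)}
    dwh = {i: float(rng.uniform(0.0, 0.2)) for i in dw}
    model = exchange.TwoStateExchangeModel(
        p_b=0.166, k_ex=1000.0 / 1.19, dw_x_ppm=dw, dw_h_ppm=dwh,
        r2_0={(p, b): 10.0 for p in dw for b in (16.4, 18.8)})
    data = synth.gen_dispersion(model, "MQ_13C1H", (16.4, 18.8), synth.NU_MQ,
                                noise=0.02, seed=SEED + 6)
    fit = exchange.fit_dispersion_global(data, "MQ_13C1H")
    print(f"methyl MQ: tau_ex = {fit.tau_ex_ms:.2f} ms (generated 1.19), "
          f"p_B = {100*fit.p_b:.1f}% (generated 16.6%)")
    (OUT / "methyl_dynamics.json").write_text(json.dumps({
        "mean_s2_tauc_ns": mean_s2tc, "tau_c_d2o_ns": tc_d2o * 1e9,
        "mq_tau_ex_ms": fit.tau_ex_ms, "mq_p_b_pct": 100 * fit.p_b,
        "seed": SEED}, indent=2))
    print(f"wrote {OUT/'methyl_ccr.csv'} and methyl_dynamics.json")


if __name__ == "__main__":
    main()
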