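#!/usr/bin/env python
"""PRE attenuation profiling: spin-label and Gd3+ broadening patterns.

Generates per-residue paramagnetic/diamagnetic intensity-ratio patterns
emulating (i) a nitroxide label reporting on the amino-terminal helix and
(ii) Gd3+ substitution into the metal site broadening residues 412-430 and
329-369, applies acquisition corrections, classifies attenuation, and
reports contiguous strongly-attenuated segments.
"""
import json
from pathlib import Path

import numpy as np

from nmrdyn import pre, synth, tables

SEED = 20240606
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    residues = np.arange(134, 459)

    # Gd3+ scenario: two broadened stretches on a quiet background
    data = synth.gen_pre(residues, [(412, 430), (329, 369)],
                         ratio_attenuated=0.1, noise=0.02, seed=SEED)
    # emulate differing acquisition settings between the para/dia spectra
    data["scan_correction"] = 2.0
    data["I_para"] = data["I_para"] / 2.0
    profile, segments = pre.attenuation_profile(data)
    strong = (profile["class"] == "strong").sum()
    print(f"Gd3+ pattern: {strong} strongly attenuated residues, "
          f"segments {segments}")
    tables.write_results(profile, OUT / "pre_gd_profile.csv")

    # moderate global attenuation (e.g. Cu2+-type paramagnetic relaxation)
    flat = synth.gen_pre(residues, [], ratio_background=0.4, noise=0.02,
                         seed=SEED + 1)
    prof2, seg2 = pre.attenuation_profile(flat)
    mean_att = prof2["attenuation_pct"].mean()
    print(f"uniform attenuation control: mean attenuation {mean_att:.0f}% "
          f"(generated 60%), {len(seg2)} strong segments")

    (OUT / "pre_segments.json").write_text(json.dumps({
        "gd_segments": segments, "uniform_mean_attenuation_pct": mean_att,
        "seed": SEED}, indent=2))
    print(f"wrote {OUT/'pre_gd_profile.csv'} and pre_segments.json")


if __name__ == "__main__":
    main()
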