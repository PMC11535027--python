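# nmrdyn

Quantitative analysis of solution-NMR protein dynamics and binding, built
around the data types of a dynamics study of the mitochondrial protease
HtrA2 and its substrate-recognition PDZ domain: relaxation decays, CPMG
relaxation-dispersion profiles, exchange lineshapes, methyl SQ/TQ
cross-correlation curves, chemical-shift tables, SEC-MALS mass series,
fluorescence progress curves, and PRE intensity pairs.

Every fitting stage is paired with a seeded synthetic-data generator whose
defaults are the study's measured conditions, so the whole pipeline is
verifiable end-to-end by parameter recovery without any external data.

## What it computes

* **Relaxation rates** (`nmrdyn.rates`) — mono-exponential fits of
  R1/R1ρ/TRACT decays with Monte-Carlo errors; R2 from R1ρ via
  R2 = R1ρ/sin²θ − R1/tan²θ with θ = atan(ω/Ω); hetNOE ratios; constant-time
  CPMG R2eff = −ln(I/I0)/T; ΔR2eff and R1·R2β diagnostics; TRACT
  rotational-correlation times from η_xy = (R2β − R2α)/2.
* **Model-free analysis** (`nmrdyn.modelfree`) — Lipari–Szabo spectral
  density J(ω) = (2/5)[S²τ/(1+(ωτ)²) + (1−S²)τ′/(1+(ωτ′)²)] under isotropic
  or axially symmetric tumbling, R2/R1 > 30 probe filtering, per-probe model
  selection M1{S²} … M4{S², τe, Rex} by AICc, and a global tensor fit.
* **Two-site exchange** (`nmrdyn.exchange`) — numerical Bloch–McConnell
  propagation of SQ (backbone ¹⁵N) and MQ (methyl ¹³C-¹H, ZQ/DQ average)
  coherences through CPMG echo trains; global dispersion fits sharing
  (p_B, k_ex) across probes and fields; Carver–Richards and Luz–Meiboom
  closed forms as independent cross-checks; two-state binding lineshape
  titrations fitted jointly for (K_D, k_off).
* **Methyl side-chain dynamics** (`nmrdyn.ccr`) — SQ/TQ intensity-ratio
  build-up |Ia/Ib| = ¾·η·tanh(λT)/(λ − δ·tanh(λT)), λ = √(η²+δ²), and the
  linear conversion of η to S²axis·τc through the intra-methyl ¹H-¹H dipolar
  prefactor (r_HH = 1.813 Å, Θ = 90°).
* **Chemical-shift analytics** (`nmrdyn.chemshift`) — CSPs
  √(ΔδH² + (ΔδX/k)²) with k = 5 (¹⁵N) or 4 (¹³C), significance flagging
  against mean + n·SD with an iterative corrected-to-zero mode, 1-2-1
  smoothed Cα/Cβ secondary shifts, Ile-δ1/Met-ε rotamer populations from
  linear ¹³C-shift calibrations, and methyl NOE contact-network differencing.
* **Equilibria & kinetics** (`nmrdyn.kinetics`) — monomer–dimer SEC-MALS
  fits of Mw([M]) with fixed endpoint masses and lower-limit detection;
  fluorescence calibration, initial rates, Michaelis–Menten and one-site
  activation fits with k_cat = v_max/[trimer]; gel percent-cleaved.
* **PRE profiling** (`nmrdyn.pre`) — corrected I_para/I_dia ratios and
  contiguous-segment detection of strongly attenuated residue runs.
* **Synthetic data** (`nmrdyn.synth`) — seeded generators for every input
  class with the measured conditions as defaults.

## Worked example

Global two-site fit of synthetic two-field backbone dispersion data at the
298 K condition (τ_ex = 0.42 ms, p_B = 15.2%, ten probes, 2% noise):

```python
import numpy as np
from nmrdyn import exchange, synth

rng = np.random.default_rng(7)
dw = {i: float(rng.uniform(1.0, 3.0)) for i in range(1, 11)}
model = exchange.TwoStateExchangeModel(
    p_b=0.152, k_ex=1000 / 0.42, dw_x_ppm=dw,
    r2_0={(p, b): 10.0 for p in dw for b in (16.4, 21.1)})
data = synth.gen_dispersion(model, "SQ_15N", (16.4, 21.1), synth.NU_SQ,
                            noise=0.02, seed=5)
fit = exchange.fit_dispersion_global(data, "SQ_15N")
print(f"tau_ex = {fit.tau_ex_ms:.3f} ms, p_B = {100*fit.p_b:.1f}%")
```

```
tau_ex = 0.421 ms, p_B = 15.3%
```

The fitter recovers the generating exchange timescale (0.42 ms) and minor
population (15.2%) from the noisy profiles; per-probe Δω values come back
within ~1% (`fit.dw_x_ppm`).

The numbered drivers under `analysis/` run the full study-shaped analyses
(backbone relaxation → model-free, two-temperature CPMG, methyl dynamics,
shift analytics, binding titrations, oligomerization, activation kinetics,
PRE profiles) and write their tables to `results/`:

```bash
python analysis/01_backbone_relaxation.py
# TRACT tau_c cross-check: 8.20 ns
# R2/R1 filter: 80 retained, 0 excluded
# model-free: tau_c = 8.22 ns (generated at 8.2), mean S2 = 0.891 (generated at ~0.9)
```

A thin CLI mirrors the library (`nmrdyn simulate`, `nmrdyn fit-dispersion`,
`nmrdyn fit-modelfree`, `nmrdyn csp`, `nmrdyn fit-mals`, ... each with
`--config/--seed/--out`).

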