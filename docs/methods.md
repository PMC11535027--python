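# Methods

This note records the models implemented in `nmrdyn`, their assumptions,
the numerical choices made where the design was genuinely open, and what
the synthetic-data validation does and does not demonstrate.

## Relaxation rates and TRACT

Intensity decays are fitted to I(t) = I0·e^(−Rt) by unweighted nonlinear
least squares (χ² weighting when per-point σ is supplied), seeded from a
log-linear regression. Negative fitted rates are reported with a
`negative_rate` flag, never clipped: a sign error is diagnostic of a bad
peak, and silently repairing it would hide that. Uncertainties come from
Monte-Carlo resampling: the fitted model is perturbed with Gaussian noise
at the stated σ and refitted; the parameter SD over replicates (default
200 draws, seeded) is the reported error. In the small-noise regime this
scales linearly with σ, which the suite checks.

R2 is derived from R1ρ with the off-resonance correction
R2 = R1ρ/sin²θ − R1/tan²θ, θ = atan(ω/Ω), defaulting to the 2 kHz
spin-lock used in the underlying experiments; on resonance this reduces to
R2 = R1ρ exactly. hetNOE errors are the standard quadrature propagation of
the two spectral-noise terms.

TRACT rates give the DD/CSA transverse cross-correlation rate
η_xy = (R2β − R2α)/2, inverted for τc through

η_xy = (1/6)·P2(cos θ)·d·ωN·Δσ·(4J(0) + 3J(ωN)),

with d = (μ0/4π)γHγNħ/r³, J(ω) = (2/5)τc/(1+(ωτc)²). The constants
(r_NH = 1.02 Å, Δσ = −172 ppm, θ = 17°) are the standard literature values;
at τc = 8.2 ns and 16.4 T this gives η_xy ≈ 11 s⁻¹, the expected scale for
a ~12 kDa domain. The inversion brackets τc in [0.1, 200] ns; R2β ≤ R2α is
flagged unphysical rather than raised, since baseline noise can produce it
probe-by-probe.

## Model-free analysis

The spectral density is the Lipari–Szabo form per diffusion branch. For
axially symmetric (prolate) tumbling the three Lorentzian branches carry
weights P2(cos α)², 3sin²α cos²α, (3/4)sin⁴α with correlation times
1/(6D⊥), 1/(5D⊥+D∥), 1/(2D⊥+4D∥); α is the angle between the N–H vector
(from the structure, with amide protons rebuilt at 1.02 Å opposite the
N-CA/N-C(i−1) bisector when absent) and the unique axis. Rex adds to R2
scaled by (B0/16.4 T)².

Probes with R2/R1 strictly above 30 are excluded before fitting (boundary
value retained). The global fit alternates (1) per-probe fits of the four
standard models M1{S²}, M2{S²,τe}, M3{S²,Rex}, M4{S²,τe,Rex} selected by
small-sample-corrected AIC, and (2) scalar (isotropic) or Nelder–Mead
(axial) refinement of the tensor over the summed selected-model χ², until
the effective τc moves by <0.1%. τc is seeded by numerically inverting the
rigid-rotor R2/R1 ratio at the trimmed-mean observed ratio. With only one
field (3 observables) AICc cannot justify 2- and 3-parameter models
(n−k−1 ≤ 0) and they are effectively excluded; Rex detection therefore
requires two-field data, which is how the suite exercises it. When no
per-point errors are given, residuals are scaled by 2% of each observable
so the three heterogeneous observables contribute comparably.

## Two-site exchange

Conventions: k_ex = k_AB + k_BA, τ_ex = 1/k_ex, p_B < 0.5;
ν_CPMG = 1/(2δ) with δ the spacing of ideal, instantaneous 180° pulses, so
a constant-time block T holds n = 2Tν pulses (even n expected; odd counts
are handled but warned about). R1 during T is neglected — the constant-time
reference cancels it in the R2eff definition.

The SQ engine propagates the two-state in-phase magnetization with the
analytic 2×2 complex matrix exponential; refocusing is complex conjugation,
so an echo pair is U·Ū·Ū·U, raised to n/2. R2eff = −ln|M_A(T)/p_A|/T. The
MQ engine tracks one coherence amplitude whose state-B precession frequency
alternates between Δω_H + Δω_C (DQ) and Δω_H − Δω_C (ZQ) at each ¹³C pulse;
the single mid-train ¹H 180° conjugates the amplitude and swaps the label.
The reported MQ R2eff is the DQ/ZQ-start average. With Δω_H = 0 this
reduces to the SQ result to machine precision, which the suite asserts.

The Carver–Richards and Luz–Meiboom closed forms are implemented purely as
cross-checks. Carver–Richards is the dominant-eigenvalue asymptotics of the
echo-train propagator and ignores the projection of the initial condition
onto the faster-decaying mode; at low pulse numbers (n ≲ 10) and large
minor populations that neglect reaches several percent of R2eff, so the
equivalence tests compare at ν ≥ 750 Hz where it is <1%. This is a property
of the closed form, not of the propagator — Luz–Meiboom agrees with the
propagator to <0.1% in its fast-exchange regime at all pulse rates.

Global dispersion fits share (p_B, k_ex); Δω is per-probe in ppm (hence
field-consistent), and the intrinsic R2_0 per probe and field enters purely
additively, so it is profiled out in closed form (weighted mean of
data − exchange term). The fit first screens a log-spaced k_ex × p_B grid
(Δω by scalar search per probe), then refines everything jointly with
bounded least squares. Flat profiles within noise raise a degenerate-fit
error instead of returning an uninterpretable optimum. Dispersion errors,
when requested, come from Monte-Carlo refits of noise-perturbed profiles.

## Binding lineshapes

Titration points are 1D steady-state two-state spectra
Re[1ᵀ(iωI − L)⁻¹ p] with L carrying the free/bound frequencies, R2 values,
and exchange rates k_on·L_free (free→bound) and k_off; L_free solves the
1:1 quadratic equilibrium exactly. Spectra conserve total integral across a
titration (each eigenline integrates to π regardless of width), which the
suite verifies on a tail-capturing grid. Fitting is joint over all points
for (K_D, k_off) on log scales with one global amplitude, multi-started
around the initial guess; peak positions and widths can optionally float.
This is a deliberate 1D approximation of full 2D lineshape fitting — with
on-resonance 1D traces the information content for (K_D, k_off) is
equivalent for well-separated single resonances, but overlapping
multi-spin systems are out of scope and the output records the
approximation.

## Methyl SQ/TQ cross-correlation

The ratio build-up equation and its (η, δ ≥ 0) least-squares fit are exact
inversions of each other at zero noise. The η → S²axis·τc conversion uses
the squared dipolar prefactor (μ0/4π)²γH⁴ħ²P2(cos 90°)²·(9/10)/r_HH⁶ — a
first-power prefactor is dimensionally inconsistent with η in s⁻¹ — giving
η = 15.52 s⁻¹ at S²axis·τc = 4.3 ns with r_HH = 1.813 Å. The default
D2O/H2O viscosity ratio for tumbling-time correction is 1.23 (298 K).

## Chemical-shift analytics

CSP significance is mean + k·SD over the CSP distribution (k = 1 or 2).
The "corrected to zero" mode recomputes mean/SD over not-yet-flagged
records until stable, which approximates the practice of zeroing large
perturbations before estimating the background spread; a single-pass mode
is kept because the iterative variant deliberately trades specificity for
sensitivity (background records near the trimmed threshold get co-flagged).
Secondary shifts combine (δCα−δCα,rc) − (δCβ−δCβ,rc) and smooth with
1-2-1 weights, renormalising at chain termini and gaps. Rotamer populations
invert the linear ¹³C calibrations δ_obs = 15.9 + 3.6·p_trans (Met-ε) and
δ_obs = 9.3 + 5.5·p_trans (Ile-δ1), clamping out-of-range values to [0, 1]
with a warning (real shifts exceed calibration endpoints); classes are
trans ≥ 0.75, gauche(−) ≤ 0.25, mixed between. Random-coil references are
an input table, never predicted internally.

## Oligomer equilibria and kinetics

The SEC-MALS model fixes both endpoint masses at the sequence values and
fits only K_D (log-parameterised), with a t-based 95% CI from the fit
covariance. A dataset is declared a lower limit when the upper CI bound
exceeds 10× the highest tested concentration — a package convention chosen
so that a transition resolved within the tested range never triggers it,
while a solubility-limited tail always does. Initial rates use a linear fit
over the <10% conversion window (auto-widened with a warning when too few
points qualify); against an integrated rate-law oracle this underestimates
the true v0 by <5%. k_cat divides v_max by the trimeric enzyme
concentration (= monomer/3), and the invariant k_cat·[trimer] = v_max holds
exactly in every fit object.

## PRE profiling

Corrections (pulse length, scan count, dilution) multiply the paramagnetic
intensity onto the diamagnetic scale; ratios above 1 are reported as-is.
Class thresholds default to strong <0.3, moderate 0.3–0.7 — the source
data are colour gradients without numeric cutoffs, so these are package
conventions — and contiguous runs of ≥3 strong residues are reported as
segments, matching how broadened stretches are described in practice.

## Synthetic data and what the tests show

Generators add Gaussian noise (default 2% of the maximum signal; 1% for
MALS and lineshapes, 3% for kinetics rates, mirroring the relative quality
of those data types) to exact forward simulations, and echo all generating
parameters in a manifest. Scenario defaults are the measured study
conditions: τc = 8.2 ns and mean S² = 0.9 ± 0.1 for the isolated domain;
backbone exchange at 0.98 ms/16.1% (283 K) and 0.42 ms/15.2% (298 K);
methyl MQ exchange at 1.19 ms/16.6%; S²axis·τc = 4.3 ns; dimer K_D = 13 mM
at 12.1 kDa over 50–600 µM; peptide binding at K_D = 3.18 µM,
k_off = 48.5 s⁻¹ (metals: 4.1/1.6 mM); kinetics at K_m = 20 µM with
k_cat/K_m = 85 M⁻¹s⁻¹ at 510 nM monomeric enzyme, substrate
0.5–30 µM and activator 5–300 µM grids.

Passing parameter recovery under these conditions demonstrates that each
fitter inverts its own forward model at realistic noise, grids and problem
sizes (80 relaxation probes, 10 SQ/8 MQ dispersion probes at two fields,
20 CCR curves, 12 MALS points, 8 titration points — sizes chosen to match
the study's data density). It does not demonstrate robustness to the
non-idealities of real spectra — peak overlap, baseline distortions,
off-resonance pulse effects, temperature drift, or model misspecification
(three-state exchange, anisotropic tumbling beyond axial symmetry) — none
of which the generators emulate.

## Known limitations

Extended model-free (two internal timescales) and fully anisotropic
diffusion are not implemented. CPMG pulses are ideal; off-resonance R1ρ
dispersion, CEST and TROSY-selective exchange effects are out of scope.
Lineshape fitting is 1D. Only the monomer–dimer (not higher-oligomer)
MALS model is provided, and no PRE→distance conversion is attempted.
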