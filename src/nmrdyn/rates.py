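"""Per-probe relaxation-rate fitting and derived diagnostics.

Mono-exponential intensity decays (R1, R1ρ, TRACT α/β), R2 from R1ρ with
off-resonance correction, steady-state hetNOE ratios, constant-time CPMG
R2eff, the R1·R2β product, and TRACT-based rotational correlation times.
Uncertainties come from seeded Monte-Carlo resampling of the input noise.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from . import constants as K

__all__ = [
    "RateFit",
    "SpinLockSettings",
    "HetNOEResult",
    "fit_monoexponential",
    "r2_from_r1rho",
    "hetnoe",
    "r2eff_from_intensities",
    "delta_r2eff",
    "r1r2_product",
    "tract_eta_xy",
    "tract_tc",
    "montecarlo_errors",
]


@dataclass
class RateFit:
    """Result of a mono-exponential decay fit."""

    probe: object
    rate: float  # s^-1
    rate_error: float = 0.0
    amplitude: float = 1.0
    amplitude_error: float = 0.0
    residual_rms: float = 0.0
    flags: list = field(default_factory=list)


@dataclass
class SpinLockSettings:
    """R1ρ spin-lock parameters: field strength and per-probe offset, both Hz."""

    omega_sl_hz: float = 2000.0
    offset_hz: float = 0.0

    def __post_init__(self):
        if self.omega_sl_hz <= 0:
            raise ValueError("spin-lock field strength must be positive")


@dataclass
class HetNOEResult:
    probe: object
    noe_ratio: float
    noe_error: float = 0.0


class FitError(RuntimeError):
    pass


def _monoexp(t, i0, r):
    return i0 * np.exp(-r * t)


def fit_monoexponential(
    delays: np.ndarray,
    intensities: np.ndarray,
    sigma: float | np.ndarray | None = None,
    probe: object = None,
    n_mc: int = 0,
    seed: int | None = None,
) -> RateFit:
    """Least-squares fit of I(t) = I0·exp(−R·t).

    Needs >= 3 delays.  A constant trace is flagged ``degenerate``; a negative
    fitted rate is flagged ``negative_rate`` but reported as-is (never
    silently clipped).  With ``n_mc > 0`` the rate error is the SD of refits
    over Gaussian noise replicates at the stated sigma (seed-reproducible).
    """
    t = np.asarray(delays, float)
    y = np.asarray(intensities, float)
    if len(t) < 3:
        raise ValueError("need at least 3 delay points")
    if np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("delays must be non-negative and strictly increasing")
    if np.ptp(y) == 0:
        return RateFit(probe, 0.0, 0.0, float(y[0]), flags=["degenerate"])
    # log-linear start; guard against non-positive intensities
    with np.errstate(divide="ignore", invalid="ignore"):
        mask = y > 0
        if mask.sum() >= 2:
            slope, intercept = np.polyfit(t[mask], np.log(y[mask]), 1)
            p0 = (math.exp(intercept), -slope)
        else:
            p0 = (float(y[0]), 1.0)
    try:
        popt, pcov = curve_fit(_monoexp, t, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"mono-exponential fit failed for probe {probe}: {exc}") from exc
    i0, r = popt
    resid = y - _monoexp(t, *popt)
    fit = RateFit(probe, float(r), 0.0, float(i0), residual_rms=float(np.sqrt(np.mean(resid**2))))
    if r <= 0:
        fit.flags.append("negative_rate")
    perr = np.sqrt(np.diag(pcov))
    fit.amplitude_error, fit.rate_error = float(perr[0]), float(perr[1])
    if n_mc and sigma is not None:
        sig = montecarlo_errors(
            lambda yy: curve_fit(_monoexp, t, yy, p0=popt, maxfev=10000)[0],
            _monoexp(t, *popt),
            sigma,
            n_draws=n_mc,
            seed=seed,
        )
        fit.amplitude_error, fit.rate_error = float(sig[0]), float(sig[1])
    return fit


def r2_from_r1rho(
    r1rho: float,
    r1: float,
    sl: SpinLockSettings,
    r1rho_err: float = 0.0,
    r1_err: float = 0.0,
) -> tuple[float, float]:
    """Off-resonance-corrected R2 from R1ρ and R1.

    θ = atan(ω/Ω) is the tilt of the effective field (ω spin-lock strength,
    Ω resonance offset, both Hz);  R2 = R1ρ/sin²θ − R1/tan²θ.  On resonance
    (Ω = 0, θ = 90°) this reduces to R2 = R1ρ exactly.  Errors propagate in
    quadrature with the fixed trigonometric coefficients.
    """
    omega, offset = sl.omega_sl_hz, sl.offset_hz
    if omega == 0 and offset == 0:
        raise ValueError("spin-lock field and offset cannot both be zero (undefined angle)")
    if offset == 0:
        return float(r1rho), float(r1rho_err)
    theta = math.atan2(omega, offset)
    a = 1.0 / math.sin(theta) ** 2
    b = 1.0 / math.tan(theta) ** 2
    r2 = a * r1rho - b * r1
    err = math.hypot(a * r1rho_err, b * r1_err)
    return float(r2), float(err)


def hetnoe(i_sat: float, i_ref: float, sigma_sat: float = 0.0, sigma_ref: float = 0.0,
           probe: object = None) -> HetNOEResult:
    """Steady-state heteronuclear NOE ratio I_sat/I_ref with quadrature error.

    Negative ratios (flexible termini) pass through with their sign.
    """
    if i_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    ratio = i_sat / i_ref
    if i_sat == 0:
        err = abs(sigma_sat / i_ref)
    else:
        err = abs(ratio) * math.hypot(sigma_sat / i_sat, sigma_ref / i_ref)
    return HetNOEResult(probe, float(ratio), float(err))


def r2eff_from_intensities(i: float, i0: float, t_relax: float) -> float:
    """Constant-time CPMG effective rate R2eff = −(1/T)·ln(I/I0)."""
    if i <= 0 or i0 <= 0 or t_relax <= 0:
        raise ValueError("intensities and constant-time period must be positive")
    return -math.log(i / i0) / t_relax


def delta_r2eff(nu_cpmg: np.ndarray, r2eff: np.ndarray) -> float:
    """Dispersion amplitude ΔR2eff = R2eff(ν_min) − R2eff(ν_max).

    Input order is irrelevant; the profile is sorted internally.
    """
    nu = np.asarray(nu_cpmg, float)
    r = np.asarray(r2eff, float)
    if len(nu) < 2:
        raise ValueError("need at least two CPMG frequencies")
    order = np.argsort(nu)
    return float(r[order[0]] - r[order[-1]])


def r1r2_product(r1: float, r2: float, r1_err: float = 0.0, r2_err: float = 0.0) -> tuple[float, float]:
    """Elementwise R1·R2β with quadrature error propagation."""
    prod = r1 * r2
    err = math.hypot(r2 * r1_err, r1 * r2_err)
    return float(prod), float(err)


# ---------------------------------------------------------------------------
# TRACT
# ---------------------------------------------------------------------------

def _rigid_j(omega: float, tau_c: float) -> float:
    """Rigid-rotor spectral density J(ω) = (2/5)·τc/(1+(ωτc)²)."""
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


def tract_eta_xy(tau_c: float, b0: float) -> float:
    """Forward 15N DD/CSA transverse cross-correlation rate η_xy(τc, B0).

    With the dipolar constant d = (μ0/4π)·γH·γN·ħ/r³ and the CSA frequency
    ω_N·Δσ, the transverse cross-correlation rate for rigid isotropic
    tumbling is

        η_xy = (1/6)·P2(cos θ)·d·ω_N·Δσ·(4J(0) + 3J(ω_N)),

    the cross term of the d²/8 dipolar and c²/6 CSA auto-relaxation
    pathways (θ = DD/CSA axis angle; J includes the 2/5 normalisation).
    R2β − R2α = 2·η_xy.
    """
    omega_n = abs(K.GAMMA_N) * b0
    d = K.MU0_OVER_4PI * K.GAMMA_H * abs(K.GAMMA_N) * K.HBAR / K.R_NH**3
    p2 = K.p2(math.cos(math.radians(K.THETA_DD_CSA_DEG)))
    return (d * omega_n * abs(K.CSA_N) / 6.0) * p2 * (
        4.0 * _rigid_j(0.0, tau_c) + 3.0 * _rigid_j(omega_n, tau_c)
    )


def tract_tc(
    r2_alpha: float,
    r2_beta: float,
    b0: float,
    tc_bracket: tuple[float, float] = (0.1e-9, 200e-9),
) -> dict:
    """Rotational correlation time from TROSY/anti-TROSY rates.

    η_xy = (R2β − R2α)/2 is inverted through :func:`tract_eta_xy` by root
    bracketing.  R2β <= R2α is unphysical and returns a flagged result with
    τc = NaN rather than raising.
    """
    eta = 0.5 * (r2_beta - r2_alpha)
    if eta <= 0:
        return {"eta_xy": float(eta), "tau_c": float("nan"), "flags": ["unphysical_eta"]}
    lo, hi = tc_bracket
    f = lambda tc: tract_eta_xy(tc, b0) - eta
    if f(lo) * f(hi) > 0:
        return {"eta_xy": float(eta), "tau_c": float("nan"), "flags": ["outside_bracket"]}
    tc = brentq(f, lo, hi, xtol=1e-14)
    return {"eta_xy": float(eta), "tau_c": float(tc), "flags": []}


def montecarlo_errors(
    fit_function,
    model_values: np.ndarray,
    sigma: float | np.ndarray,
    n_draws: int = 200,
    seed: int | None = None,
    max_failure_fraction: float = 0.10,
) -> np.ndarray:
    """Monte-Carlo parameter uncertainties.

    ``fit_function(y) -> parameter vector`` is re-run on ``n_draws``
    noise-perturbed replicates of ``model_values`` (Gaussian, SD ``sigma``);
    returns the SD of each parameter over replicates.  Requires
    ``n_draws >= 50``; more than 10% replicate failures raises.
    """
    if n_draws < 50:
        raise ValueError("Monte-Carlo error estimation needs n_draws >= 50")
    rng = np.random.default_rng(seed)
    base = np.asarray(model_values, float)
    results, failures = [], 0
    for _ in range(n_draws):
        y = base + rng.normal(0.0, sigma, size=base.shape)
        try:
            results.append(np.asarray(fit_function(y), float))
        except Exception:
            failures += 1
    if failures > max_failure_fraction * n_draws:
        raise FitError(f"{failures}/{n_draws} Monte-Carlo replicates failed to converge")
    return np.std(np.asarray(results), axis=0, ddof=1)
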