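"""Oligomer equilibria and protease activation kinetics.

SEC-MALS monomer–dimer fitting, fluorescence calibration of cleavage
progress curves, initial-rate extraction, Michaelis–Menten and one-site
activation fits, catalytic constants, and gel-band cleavage percentages.

The weight-average mass of a fast monomer–dimer equilibrium at monomer
(formula-unit) concentration [M] is

    Mw = 2M − M·(−K_D + √(K_D² + 8·[M]·K_D)) / (4·[M])

which runs from M at infinite dilution to 2M at saturation, passing 1.5·M
at [M] = K_D.  Catalytic constants follow k_cat = v_max/[E_trimer] with the
trimer concentration = monomer/3.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

__all__ = [
    "DimerFit",
    "KineticFit",
    "mw_monomer_dimer",
    "fit_dimer_kd",
    "calibrate_fluorescence",
    "initial_rate",
    "fit_michaelis_menten",
    "fit_activation",
    "gel_cleavage_fraction",
]


@dataclass
class DimerFit:
    k_d: float  # M
    ci95: tuple  # (low, high), M
    lower_limit_flag: bool
    monomer_mass: float  # Da


@dataclass
class KineticFit:
    v_max: float = 0.0  # M/s
    v_max_err: float = 0.0
    k_m: float = 0.0  # M
    k_m_err: float = 0.0
    k_cat: float = 0.0  # s^-1
    k_cat_over_km: float = 0.0  # M^-1 s^-1
    k_max: float = 0.0  # s^-1 (activation fits)
    k_0: float = 0.0  # s^-1
    k_d_app: float = 0.0  # M
    errors: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def mw_monomer_dimer(monomer_mass: float, conc: float | np.ndarray, k_d: float):
    """Weight-average mass of a fast monomer–dimer equilibrium.

    ``conc`` is the total monomer-unit concentration (M); the [M] → 0 limit
    (Mw = monomer mass) is handled analytically.
    """
    if monomer_mass <= 0 or k_d <= 0:
        raise ValueError("monomer mass and K_D must be positive")
    c = np.asarray(conc, float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.empty_like(c)
    zero = c == 0
    out[zero] = monomer_mass
    cz = c[~zero]
    out[~zero] = 2.0 * monomer_mass - monomer_mass * (
        -k_d + np.sqrt(k_d * k_d + 8.0 * cz * k_d)
    ) / (4.0 * cz)
    return float(out[0]) if scalar else out


def fit_dimer_kd(
    conc: np.ndarray,
    mw_obs: np.ndarray,
    monomer_mass: float,
    lower_limit_factor: float = 10.0,
) -> DimerFit:
    """Constrained-endpoint monomer–dimer K_D fit to a SEC-MALS series.

    The endpoint masses (M, 2M) are fixed from the sequence mass; only K_D
    is free.  The 95% CI comes from the fit covariance (t-distribution).
    When the upper CI bound exceeds ``lower_limit_factor`` × the highest
    tested concentration, the result is flagged as a lower limit (the
    dataset is solubility-limited and only bounds K_D from below).  A
    decreasing Mw trend triggers a model-violation warning.
    """
    c = np.asarray(conc, float)
    mw = np.asarray(mw_obs, float)
    if len(c) < 4:
        raise ValueError("need at least 4 concentration points")
    slope = np.polyfit(c, mw, 1)[0]
    if slope < 0:
        warnings.warn("Mw decreases with concentration; monomer-dimer model violated")

    def f(x, log_kd):
        return mw_monomer_dimer(monomer_mass, x, math.exp(log_kd))

    # start from the concentration scale; log-parameterised for positivity
    popt, pcov = curve_fit(f, c, mw, p0=[math.log(np.median(c) * 10)], maxfev=10000)
    log_kd, var = float(popt[0]), float(pcov[0, 0])
    kd = math.exp(log_kd)
    dof = max(len(c) - 1, 1)
    half = t_dist.ppf(0.975, dof) * math.sqrt(max(var, 0.0))
    ci = (kd * math.exp(-half), kd * math.exp(half))
    flag = ci[1] > lower_limit_factor * float(c.max())
    return DimerFit(kd, ci, bool(flag), monomer_mass)


def calibrate_fluorescence(
    fluorescence: np.ndarray,
    f_uncleaved: float,
    f_complete: float,
    substrate_total: float,
) -> np.ndarray:
    """Map raw fluorescence to product concentration.

    [P](t) = S_total·(F − F_uncleaved)/(F_complete − F_uncleaved), clipped
    to [0, S_total]; out-of-band values warn.
    """
    if f_complete == f_uncleaved:
        raise ValueError("zero calibration span (uncleaved and complete signals equal)")
    f = np.asarray(fluorescence, float)
    p = substrate_total * (f - f_uncleaved) / (f_complete - f_uncleaved)
    if np.any(p < -1e-12) or np.any(p > substrate_total * (1 + 1e-12)):
        warnings.warn("fluorescence outside the calibration band; product clipped")
    return np.clip(p, 0.0, substrate_total)


def initial_rate(
    time: np.ndarray,
    product: np.ndarray,
    substrate_total: float,
    conversion_window: float = 0.10,
    min_points: int = 5,
) -> tuple[float, float, dict]:
    """Initial velocity from the early linear part of a progress curve.

    Fits a line over the window where product < ``conversion_window`` ×
    substrate; if fewer than ``min_points`` qualify the window widens with a
    warning.  Returns (v0, sigma_v0, window_info).
    """
    t = np.asarray(time, float)
    p = np.asarray(product, float)
    limit = conversion_window * substrate_total
    mask = p < limit
    widened = False
    while mask.sum() < min_points and limit < substrate_total:
        limit *= 1.5
        mask = p < limit
        widened = True
    if widened:
        warnings.warn("initial-rate window widened to reach the minimum point count")
    if mask.sum() < 2:
        raise ValueError("too few points for an initial-rate fit")
    coef, cov = np.polyfit(t[mask], p[mask], 1, cov=True)
    info = {"n_points": int(mask.sum()), "conversion_limit": float(limit / substrate_total),
            "widened": widened}
    return float(coef[0]), float(math.sqrt(max(cov[0, 0], 0.0))), info


def fit_michaelis_menten(
    substrate: np.ndarray,
    rates: np.ndarray,
    enzyme_monomer: float,
    rate_sigma: np.ndarray | None = None,
) -> KineticFit:
    """(v_max, K_m) by nonlinear least squares; catalytic constants attached.

    k_cat = v_max/[trimer] with [trimer] = enzyme monomer concentration / 3.
    K_m more than 5× above the highest substrate level is flagged as poorly
    constrained.
    """
    s = np.asarray(substrate, float)
    v = np.asarray(rates, float)
    if len(s) < 4:
        raise ValueError("need at least 4 substrate levels")

    def mm(x, vmax, km):
        return vmax * x / (km + x)

    p0 = [v.max() * 1.5, np.median(s)]
    popt, pcov = curve_fit(mm, s, v, p0=p0, sigma=rate_sigma, maxfev=10000)
    vmax, km = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    trimer = enzyme_monomer / 3.0
    kcat = vmax / trimer
    fit = KineticFit(
        v_max=vmax, v_max_err=float(perr[0]), k_m=km, k_m_err=float(perr[1]),
        k_cat=kcat, k_cat_over_km=kcat / km,
        errors={"v_max": float(perr[0]), "K_m": float(perr[1])},
    )
    if km > 5.0 * s.max():
        fit.flags.append("km_poorly_constrained")
    return fit


def fit_activation(
    activator: np.ndarray,
    rates: np.ndarray,
    rate_sigma: np.ndarray | None = None,
    n_mc: int = 0,
    seed: int | None = None,
) -> KineticFit:
    """One-site activation fit k([A]) = k_max·[A]/(K_D,app + [A]) + k_0.

    Approximates free activator by total activator.  Needs >= 5 levels; a
    decreasing trend warns of model violation (e.g. relief-of-inhibition
    data).  Errors by Monte-Carlo when requested.
    """
    a = np.asarray(activator, float)
    k = np.asarray(rates, float)
    if len(a) < 5:
        raise ValueError("need at least 5 activator levels")
    if np.polyfit(a, k, 1)[0] < 0:
        warnings.warn("rate decreases with activator concentration; "
                      "one-site activation model violated")

    def act(x, kmax, kdapp, k0):
        return kmax * x / (kdapp + x) + k0

    p0 = [k.max() - k.min(), np.median(a), max(k.min(), 1e-12)]
    popt, pcov = curve_fit(act, a, k, p0=p0, sigma=rate_sigma, maxfev=20000)
    fit = KineticFit(k_max=float(popt[0]), k_d_app=float(popt[1]), k_0=float(popt[2]))
    perr = np.sqrt(np.diag(pcov))
    fit.errors = {"k_max": float(perr[0]), "K_D_app": float(perr[1]), "k_0": float(perr[2])}
    if n_mc and rate_sigma is not None:
        from .rates import montecarlo_errors

        model = act(a, *popt)
        sig = montecarlo_errors(
            lambda yy: curve_fit(act, a, yy, p0=popt, maxfev=20000)[0],
            model, rate_sigma, n_draws=n_mc, seed=seed,
        )
        fit.errors = {"k_max": float(sig[0]), "K_D_app": float(sig[1]), "k_0": float(sig[2])}
    return fit


def gel_cleavage_fraction(intensity_t0: float, intensity_t: float) -> float:
    """Percent substrate cleaved from intact-band intensities: 100·(1 − I_t/I_t0).

    Band intensities above the t0 reference clip to 0% with a warning.
    """
    if intensity_t0 <= 0:
        raise ValueError("t0 band intensity must be positive")
    frac = 100.0 * (1.0 - intensity_t / intensity_t0)
    if frac < 0:
        warnings.warn("band intensity grew over time; percent cleaved clipped to 0")
        return 0.0
    return float(frac)
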