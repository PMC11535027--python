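"""Methyl SQ/TQ cross-correlated relaxation analysis.

Intra-methyl 1H-1H dipolar cross-correlated relaxation (rate η) is read out
from the build-up of the ratio of triple- to single-quantum peak
intensities as a function of the relaxation delay T:

    |Ia/Ib| = (3/4)·η·tanh(√(η²+δ²)·T) / (√(η²+δ²) − δ·tanh(√(η²+δ²)·T))

where δ accounts for coupling to external protons.  η is proportional to
the product of the methyl symmetry-axis order parameter and the overall
tumbling time:

    η = (9/10)·(μ0/4π)²·P2(cos Θ_axis,HH)²·γH⁴·ħ²·S²axis·τc / r_HH⁶

with r_HH = 1.813 Å and Θ = 90°.  The dipolar prefactor is squared (the
two-interaction cross term), which gives η in s⁻¹; the conversion is exactly
linear in η.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import constants as K

__all__ = ["CCRFit", "ccr_forward", "fit_ccr", "s2tc_from_eta", "eta_from_s2tc",
           "d2o_tc_correction", "ETA_PER_S2TC"]

#: eta (s^-1) per second of S2axis*tau_c — the Eq. prefactor evaluated once
ETA_PER_S2TC = (
    0.9
    * K.MU0_OVER_4PI**2
    * K.p2(math.cos(math.radians(K.THETA_AXIS_HH_DEG))) ** 2
    * K.GAMMA_H**4
    * K.HBAR**2
    / K.R_HH_METHYL**6
)


@dataclass
class CCRFit:
    probe: object
    eta: float  # s^-1
    delta: float  # s^-1
    eta_err: float = 0.0
    delta_err: float = 0.0
    s2_tauc_ns: float = 0.0
    flags: list = field(default_factory=list)


def ccr_forward(eta: float, delta: float, t: np.ndarray) -> np.ndarray:
    """Forward SQ/TQ intensity-ratio curve |Ia/Ib|(T)."""
    t = np.asarray(t, float)
    lam = math.hypot(eta, delta)
    if lam == 0:
        return np.zeros_like(t)
    th = np.tanh(lam * t)
    return 0.75 * eta * th / (lam - delta * th)


def fit_ccr(
    delays: np.ndarray,
    ratios: np.ndarray,
    sigma: np.ndarray | float | None = None,
    probe: object = None,
    n_mc: int = 0,
    seed: int | None = None,
) -> CCRFit:
    """Least-squares fit of (η, δ) to an SQ/TQ ratio build-up curve.

    δ is constrained non-negative.  Needs >= 5 delays; an all-zero ratio
    curve is flagged degenerate.  Monte-Carlo errors over ``n_mc`` replicates
    when the per-point noise is given.
    """
    t = np.asarray(delays, float)
    y = np.asarray(ratios, float)
    if len(t) < 5:
        raise ValueError("need at least 5 delay points")
    if np.all(y == 0):
        return CCRFit(probe, 0.0, 0.0, flags=["degenerate"])

    def residuals(x):
        return ccr_forward(x[0], x[1], t) - y

    # initial eta from the small-T slope: ratio ~ (3/4) eta T
    eta0 = max(4.0 / 3.0 * y[0] / t[0], 1.0)
    sol = least_squares(residuals, [eta0, 1.0], bounds=([0.0, 0.0], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14)
    if not sol.success:
        return CCRFit(probe, float("nan"), float("nan"), flags=["non_convergence"])
    eta, delta = float(sol.x[0]), float(sol.x[1])
    fit = CCRFit(probe, eta, delta, s2_tauc_ns=s2tc_from_eta(eta))
    if n_mc and sigma is not None:
        from .rates import montecarlo_errors

        model = ccr_forward(eta, delta, t)
        sig = montecarlo_errors(
            lambda yy: least_squares(lambda x: ccr_forward(x[0], x[1], t) - yy,
                                     [eta, delta], bounds=([0, 0], [np.inf, np.inf])).x,
            model, sigma, n_draws=n_mc, seed=seed,
        )
        fit.eta_err, fit.delta_err = float(sig[0]), float(sig[1])
    return fit


def s2tc_from_eta(eta: float) -> float:
    """Convert η (s⁻¹) to S²axis·τc in ns; exactly linear."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    return eta / ETA_PER_S2TC * 1e9


def eta_from_s2tc(s2_tauc_ns: float) -> float:
    """Inverse conversion: S²axis·τc (ns) to η (s⁻¹)."""
    return s2_tauc_ns * 1e-9 * ETA_PER_S2TC


def d2o_tc_correction(tau_c: float, viscosity_ratio: float = 1.23) -> float:
    """Scale a tumbling time for the D2O/H2O solvent viscosity difference.

    Default ratio 1.23 (298 K).  ``viscosity_ratio`` must be positive.
    """
    if viscosity_ratio <= 0:
        raise ValueError("viscosity ratio must be positive")
    return tau_c * viscosity_ratio
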