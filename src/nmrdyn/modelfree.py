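"""Lipari–Szabo model-free analysis of 15N backbone relaxation.

The spectral density of internal motion on top of overall tumbling is

    J(ω) = (2/5) [ S²·τ/(1+(ωτ)²) + (1−S²)·τ'/(1+(ωτ')²) ],  1/τ' = 1/τ + 1/τe

evaluated per Lorentzian branch of the diffusion tensor (one branch for
isotropic tumbling; three branches weighted by the bond-vector angle to the
unique axis for an axially symmetric tensor).  R1, R2 and hetNOE follow from
the standard 15N dipolar + CSA expressions; an exchange term Rex adds to R2
scaled by (B0/B0_ref)².

Model selection per probe is over M1{S²}, M2{S²,τe}, M3{S²,Rex},
M4{S²,τe,Rex} by small-sample corrected AIC; the diffusion tensor and the
per-probe parameters are iterated to self-consistency.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from . import constants as K

__all__ = [
    "DiffusionTensor",
    "ModelFreeParams",
    "predict_rates",
    "filter_probes",
    "estimate_tc",
    "fit_modelfree",
    "B0_REF",
]

B0_REF = 16.4  # Tesla; reference field for Rex reporting

_MODEL_PARAMS = {"M1": ("S2",), "M2": ("S2", "tau_e"), "M3": ("S2", "Rex"),
                 "M4": ("S2", "tau_e", "Rex")}


@dataclass
class DiffusionTensor:
    """Overall rotational diffusion: isotropic or axially symmetric (prolate)."""

    mode: str = "isotropic"  # "isotropic" | "axial"
    tau_c: float = 8.2e-9  # s, isotropic-equivalent correlation time
    d_ratio: float = 1.0  # D_parallel / D_perp (>= 1, prolate)
    axis: tuple[float, float] = (0.0, 0.0)  # polar angles (theta, phi) of unique axis, rad

    def __post_init__(self):
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.mode == "axial" and self.d_ratio < 1.0:
            raise ValueError("axial tensor must be prolate (D_parallel >= D_perp)")

    @property
    def d_iso(self) -> float:
        return 1.0 / (6.0 * self.tau_c)

    @property
    def d_parallel(self) -> float:
        # D_iso = (D_par + 2 D_perp)/3 with D_par = ratio * D_perp
        return self.d_ratio * 3.0 * self.d_iso / (self.d_ratio + 2.0)

    @property
    def d_perp(self) -> float:
        return 3.0 * self.d_iso / (self.d_ratio + 2.0)

    def branches(self, vector: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """Correlation times and weights of the Lorentzian branches.

        For the axial tensor the weights depend on the angle α between the
        bond vector and the unique axis:
        A1 = P2(cos α)², τ1 = 1/(6D⊥); A2 = 3 sin²α cos²α, τ2 = 1/(5D⊥+D∥);
        A3 = (3/4) sin⁴α, τ3 = 1/(2D⊥+4D∥).
        """
        if self.mode == "isotropic":
            return np.array([self.tau_c]), np.array([1.0])
        if vector is None:
            raise ValueError("axial diffusion mode requires a bond vector per probe")
        dpar, dper = self.d_parallel, self.d_perp
        v = np.asarray(vector, float)
        v = v / np.linalg.norm(v)
        th, ph = self.axis
        axis = np.array([math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)])
        ca = float(np.dot(v, axis))
        ca2 = ca * ca
        sa2 = 1.0 - ca2
        weights = np.array([
            (1.5 * ca2 - 0.5) ** 2,
            3.0 * sa2 * ca2,
            0.75 * sa2 * sa2,
        ])
        taus = np.array([
            1.0 / (6.0 * dper),
            1.0 / (5.0 * dper + dpar),
            1.0 / (2.0 * dper + 4.0 * dpar),
        ])
        return taus, weights


@dataclass
class ModelFreeParams:
    probe: object = None
    model_id: str = "M1"
    S2: float = 1.0
    tau_e: float = 0.0  # s
    Rex: float = 0.0  # s^-1 at B0_REF
    S2_err: float = 0.0
    tau_e_err: float = 0.0
    Rex_err: float = 0.0
    chi2: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.S2 <= 1.0:
            raise ValueError("S2 must lie in [0, 1]")
        if self.tau_e < 0 or self.Rex < 0:
            raise ValueError("tau_e and Rex must be non-negative")


def _jw(omega: np.ndarray, s2: float, tau_e: float, taus: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Model-free spectral density summed over diffusion branches."""
    omega = np.asarray(omega, float)[:, None]
    taus = taus[None, :]
    j = s2 * taus / (1.0 + (omega * taus) ** 2)
    if tau_e > 0 and s2 < 1.0:
        tp = taus * tau_e / (taus + tau_e)
        j = j + (1.0 - s2) * tp / (1.0 + (omega * tp) ** 2)
    elif s2 < 1.0 and tau_e == 0.0:
        pass  # τe→0 limit: the internal term has zero spectral weight
    return 0.4 * np.sum(weights[None, :] * j, axis=1)


def predict_rates(
    params: ModelFreeParams,
    tensor: DiffusionTensor,
    b0: float,
    vector: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(R1, R2, hetNOE) for one 15N-1H probe at field ``b0`` (Tesla)."""
    taus, weights = tensor.branches(vector)
    wh = K.GAMMA_H * b0
    wn = abs(K.GAMMA_N) * b0
    d = K.MU0_OVER_4PI * K.GAMMA_H * abs(K.GAMMA_N) * K.HBAR / K.R_NH**3
    d2 = d * d
    c2 = (wn * K.CSA_N) ** 2 / 3.0
    js = _jw(np.array([0.0, wn, wh - wn, wh, wh + wn]), params.S2, params.tau_e, taus, weights)
    j0, jn, jhmn, jh, jhpn = js
    r1 = d2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = d2 / 8.0 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) + c2 / 6.0 * (
        4.0 * j0 + 3.0 * jn
    )
    r2 += params.Rex * (b0 / B0_REF) ** 2
    sigma = d2 / 4.0 * (6.0 * jhpn - jhmn)
    noe = 1.0 + (K.GAMMA_H / K.GAMMA_N) * sigma / r1
    return float(r1), float(r2), float(noe)


def filter_probes(rates: "pd.DataFrame", ratio_limit: float = 30.0,
                  noe_floor: float | None = None):
    """Partition probes into retained/excluded by the R2/R1 > limit rule.

    ``rates`` needs columns ``probe, R1, R2``; rows with R2/R1 strictly above
    the limit (default 30, the exchange-contamination cutoff) are excluded.
    An optional hetNOE floor can exclude highly flexible probes (off by
    default).  Returns ``(retained, excluded)`` DataFrames.
    """
    import pandas as pd

    if len(rates) == 0:
        return rates.copy(), rates.copy()
    if (rates["R1"] <= 0).any():
        raise ValueError("R1 must be positive for the R2/R1 filter")
    ratio = rates["R2"] / rates["R1"]
    drop = ratio > ratio_limit
    if noe_floor is not None and "hetNOE" in rates.columns:
        drop |= rates["hetNOE"] < noe_floor
    return rates.loc[~drop].copy(), rates.loc[drop].copy()


def estimate_tc(rates: "pd.DataFrame", b0: float, trim: float = 0.1) -> float:
    """Initial τc from the trimmed-mean R2/R1 ratio at a single field.

    The rigid-rotor (S² = 1, Rex = 0) ratio R2/R1 is monotone in τc; the
    trimmed mean of the observed ratios is inverted numerically.  Needs >= 5
    probes.
    """
    from scipy.optimize import brentq
    from scipy.stats import trim_mean

    if len(rates) < 5:
        raise ValueError("need at least 5 retained probes to estimate tau_c")
    ratio = trim_mean((rates["R2"] / rates["R1"]).to_numpy(float), trim)
    rigid = ModelFreeParams(S2=1.0)

    def f(tc):
        t = DiffusionTensor(tau_c=tc)
        r1, r2, _ = predict_rates(rigid, t, b0)
        return r2 / r1 - ratio

    lo, hi = 0.3e-9, 100e-9
    if f(lo) * f(hi) > 0:
        raise ValueError("observed R2/R1 ratio outside invertible range")
    return float(brentq(f, lo, hi, xtol=1e-14))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_probe_model(model_id, row, tensor, fields, vector):
    """Least-squares fit of one probe under one model; returns (params, chi2, n_par)."""
    names = _MODEL_PARAMS[model_id]
    x0, lo, hi = [], [], []
    for name in names:
        if name == "S2":
            x0.append(0.8); lo.append(0.0); hi.append(1.0)
        elif name == "tau_e":
            x0.append(50e-12); lo.append(0.0); hi.append(5e-9)
        else:  # Rex
            x0.append(1.0); lo.append(0.0); hi.append(50.0)

    y, sig = [], []
    for b0 in fields:
        for q in ("R1", "R2", "hetNOE"):
            val = row[(b0, q)]
            err = row.get((b0, q + "_err"), 0.0)
            y.append(val)
            # unweighted (fractional) residuals when no error is supplied
            sig.append(err if err > 0 else max(0.02 * abs(val), 1e-8))
    y = np.asarray(y, float)
    sig = np.asarray(sig, float)

    def residuals(x):
        kw = dict(zip(names, x))
        p = ModelFreeParams(S2=kw.get("S2", 1.0), tau_e=kw.get("tau_e", 0.0),
                            Rex=kw.get("Rex", 0.0))
        pred = []
        for b0 in fields:
            pred.extend(predict_rates(p, tensor, b0, vector))
        return (np.asarray(pred) - y) / sig

    sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    chi2 = float(np.sum(sol.fun**2))
    kw = dict(zip(names, sol.x))
    params = ModelFreeParams(
        model_id=model_id, S2=kw.get("S2", 1.0),
        tau_e=kw.get("tau_e", 0.0), Rex=kw.get("Rex", 0.0), chi2=chi2,
    )
    return params, chi2, len(names)


def _aicc(chi2: float, n_par: int, n_obs: int) -> float:
    aic = chi2 + 2.0 * n_par
    denom = n_obs - n_par - 1
    if denom <= 0:
        return aic + 1e6  # richer model than the data can support
    return aic + 2.0 * n_par * (n_par + 1) / denom


def _select_models(rows, tensor, fields, vectors, models):
    """Per-probe model selection by AICc; returns (params list, total chi2)."""
    out, total = [], 0.0
    n_obs = 3 * len(fields)
    for probe, row in rows:
        vec = vectors.get(probe) if vectors else None
        best, best_score = None, np.inf
        for mid in models:
            params, chi2, n_par = _fit_probe_model(mid, row, tensor, fields, vec)
            score = _aicc(chi2, n_par, n_obs)
            if score < best_score - 1e-12:
                best, best_score = params, score
        best.probe = probe
        out.append(best)
        total += best.chi2
    return out, total


def _prepare_rows(rates, fields):
    """Reshape a tidy rates table into per-probe {(field, quantity): value} rows."""
    rows = []
    for probe, grp in rates.groupby("probe", sort=True):
        row = {}
        for rec in grp.itertuples(index=False):
            b0 = float(rec.field_T)
            for q in ("R1", "R2", "hetNOE"):
                row[(b0, q)] = float(getattr(rec, q))
                err = getattr(rec, q + "_err", 0.0)
                row[(b0, q + "_err")] = float(err)
        if all((b0, q) in row for b0 in fields for q in ("R1", "R2", "hetNOE")):
            rows.append((probe, row))
    return rows


def fit_modelfree(
    rates: "pd.DataFrame",
    vectors: dict | None = None,
    mode: str = "isotropic",
    models: tuple = ("M1", "M2", "M3", "M4"),
    max_cycles: int = 20,
    tc_tol: float = 1e-3,
) -> tuple[DiffusionTensor, list[ModelFreeParams]]:
    """Two-stage model-free fit: diffusion tensor + per-probe parameters.

    ``rates`` is a tidy table (probe, field_T, R1, R2, hetNOE and optional
    *_err columns), already filtered by :func:`filter_probes`.  The tensor is
    first seeded from the trimmed R2/R1 ratio, then tensor and per-probe
    model-selected parameters are alternated until the effective τc changes
    by < 0.1% (relative).  ``mode`` is "isotropic" or "axial"; axial mode
    needs a ``vectors`` dict (probe -> unit vector) and also optimises the
    anisotropy D∥/D⊥ and the unique-axis orientation.
    """
    fields = sorted(set(float(b) for b in rates["field_T"]))
    rows = _prepare_rows(rates, fields)
    if not rows:
        raise ValueError("no probe has a complete (R1, R2, hetNOE) set at every field")
    if mode == "axial" and not vectors:
        raise ValueError("axial mode requires bond vectors")

    tc = estimate_tc(rates[rates["field_T"] == fields[0]], fields[0]) if len(rows) >= 5 else 8e-9

    def total_chi2_iso(tc_val):
        tensor = DiffusionTensor(mode="isotropic", tau_c=tc_val)
        _, chi2 = _select_models(rows, tensor, fields, vectors, models)
        return chi2

    if mode == "isotropic":
        prev = tc
        for _ in range(max_cycles):
            res = minimize_scalar(
                total_chi2_iso, bounds=(prev * 0.5, prev * 2.0),
                method="bounded", options={"xatol": prev * 1e-4},
            )
            tc = float(res.x)
            if abs(tc - prev) / prev < tc_tol:
                break
            prev = tc
        else:
            warnings.warn("tensor iteration did not converge; reporting last iterate")
        tensor = DiffusionTensor(mode="isotropic", tau_c=tc)
    else:
        from scipy.optimize import minimize

        def total_chi2_axial(x):
            tcv, ratio, th, ph = x
            if tcv <= 0 or ratio < 1.0:
                return 1e12
            tensor = DiffusionTensor(mode="axial", tau_c=tcv, d_ratio=ratio, axis=(th, ph))
            _, chi2 = _select_models(rows, tensor, fields, vectors, models)
            return chi2

        res = minimize(
            total_chi2_axial, [tc, 1.2, 0.5, 0.5], method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 300},
        )
        tcv, ratio, th, ph = res.x
        tensor = DiffusionTensor(mode="axial", tau_c=float(tcv), d_ratio=max(1.0, float(ratio)),
                                 axis=(float(th), float(ph)))

    params, _ = _select_models(rows, tensor, fields, vectors, models)
    return tensor, params
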