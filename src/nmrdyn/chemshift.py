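"""Chemical-shift analytics.

Chemical-shift perturbations (CSPs) between two conditions, significance
flagging against the CSP distribution, Cα/Cβ combined secondary shifts with
1-2-1 smoothing, methyl rotamer populations from 13C shifts, and methyl-methyl
NOE contact networks.

CSPs use the standard weighted Euclidean distance

    Δδ(HN) = sqrt(ΔδH² + (ΔδN/5)²)        (backbone amides)
    Δδ(HC) = sqrt(ΔδH² + (ΔδC/4)²)        (methyl groups)

Rotamer populations are read off linear calibrations of the methyl 13C shift:
Met-ε  δ_obs = 15.9 + 3.6·p_trans and Ile-δ1  δ_obs = 9.3 + 5.5·p_trans,
with p_trans ≥ 0.75 classed *trans* and ≤ 0.25 classed *gauche(−)*.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .tables import ProbeID

__all__ = [
    "compute_csp_amide",
    "compute_csp_methyl",
    "flag_significant",
    "secondary_shifts",
    "rotamer_population",
    "rotamer_delta",
    "build_noe_network",
    "diff_noe_networks",
    "ROTAMER_CALIBRATIONS",
]

# linear 13C-shift calibrations: label -> (intercept ppm, slope ppm per unit p_trans)
ROTAMER_CALIBRATIONS = {
    "Met-e": (15.9, 3.6),
    "Ile-d1": (9.3, 5.5),
}

# plausible shift ranges per nucleus (warnings only)
_PLAUSIBLE = {"1H": (-2.0, 13.0), "15N": (95.0, 140.0), "13C": (0.0, 80.0)}


class EmptyOverlapError(ValueError):
    """The two shift tables share no probes."""


def check_shift_plausibility(df: pd.DataFrame) -> None:
    """Warn (never reject) on shifts outside the plausible per-nucleus range."""
    for nuc, (lo, hi) in _PLAUSIBLE.items():
        col = df.loc[df.get("nucleus", pd.Series(dtype=str)) == nuc, "delta_obs"]
        bad = col[(col < lo) | (col > hi)]
        if len(bad):
            warnings.warn(f"{len(bad)} {nuc} shift(s) outside plausible range [{lo}, {hi}] ppm")


def _csp(reference: pd.DataFrame, perturbed: pd.DataFrame, x_col: str, divisor: float) -> pd.DataFrame:
    """Shared CSP machinery; tables indexed/joined on the 'probe' column."""
    for df, name in ((reference, "reference"), (perturbed, "perturbed")):
        for col in ("probe", "delta_H", x_col):
            if col not in df.columns:
                raise KeyError(f"{name} table lacks column {col!r}")
    merged = reference.merge(perturbed, on="probe", suffixes=("_ref", "_per"))
    if merged.empty:
        raise EmptyOverlapError("no probes shared between reference and perturbed tables")
    d_h = merged[f"delta_H_per"] - merged[f"delta_H_ref"]
    d_x = merged[f"{x_col}_per"] - merged[f"{x_col}_ref"]
    csp = np.sqrt(d_h**2 + (d_x / divisor) ** 2)
    out = pd.DataFrame(
        {
            "probe": merged["probe"],
            "delta_H": d_h,
            "delta_X": d_x,
            "csp": csp,
            "significant": "none",
        }
    )
    only_ref = sorted(set(reference["probe"]) - set(perturbed["probe"]))
    only_per = sorted(set(perturbed["probe"]) - set(reference["probe"]))
    out.attrs["unmatched_reference"] = only_ref
    out.attrs["unmatched_perturbed"] = only_per
    return out


def compute_csp_amide(reference: pd.DataFrame, perturbed: pd.DataFrame) -> pd.DataFrame:
    """Amide CSPs: sqrt(ΔδH² + (ΔδN/5)²) for probes present in both tables.

    Tables need columns ``probe``, ``delta_H``, ``delta_N`` (ppm).  Probes
    present in only one table are reported in ``result.attrs``.
    """
    return _csp(reference, perturbed, "delta_N", 5.0)


def compute_csp_methyl(reference: pd.DataFrame, perturbed: pd.DataFrame) -> pd.DataFrame:
    """Methyl CSPs: sqrt(ΔδH² + (ΔδC/4)²); columns ``probe, delta_H, delta_C``."""
    return _csp(reference, perturbed, "delta_C", 4.0)


def flag_significant(
    csps: pd.DataFrame,
    threshold_mode: str = "1SD",
    corrected_to_zero: bool = False,
    max_iter: int = 20,
) -> pd.DataFrame:
    """Flag CSPs exceeding mean + k·SD of the CSP distribution.

    ``threshold_mode`` is ``"1SD"`` or ``"2SD"``.  With ``corrected_to_zero``
    the mean/SD are recomputed iteratively over the not-yet-flagged records
    until the flagged set is stable (trimmed-threshold convention); otherwise a
    single pass over all records is used.  Needs >= 3 records.
    """
    if threshold_mode not in ("1SD", "2SD"):
        raise ValueError("threshold_mode must be '1SD' or '2SD'")
    if len(csps) < 3:
        raise ValueError("need at least 3 CSP records to estimate a distribution")
    k = 1.0 if threshold_mode == "1SD" else 2.0
    out = csps.copy()
    values = out["csp"].to_numpy(float)
    flagged = np.zeros(len(values), bool)
    for _ in range(max_iter):
        pool = values[~flagged]
        sd = pool.std(ddof=1) if len(pool) > 1 else 0.0
        if sd == 0.0:
            if not flagged.any():
                warnings.warn("CSP distribution has zero spread; nothing flagged")
            break  # unflagged pool is constant; flags are stable
        threshold = pool.mean() + k * sd
        new = values > threshold
        if not corrected_to_zero or np.array_equal(new, flagged):
            flagged = new
            break
        flagged = new
    out["significant"] = np.where(flagged, threshold_mode, "none")
    return out


def secondary_shifts(observed: pd.DataFrame, random_coil: pd.DataFrame) -> pd.DataFrame:
    """Cα/Cβ combined secondary shifts with 1-2-1 neighbour smoothing.

    Raw value per residue: (δCα − δCα,rc) − (δCβ − δCβ,rc).  Smoothing applies
    weights 1-2-1 over residues (i−1, i, i+1); missing neighbours are dropped
    and the remaining weights renormalised.  Both tables need columns
    ``residue, delta_CA, delta_CB``; residues lacking both carbons in either
    table are excluded with a warning.
    """
    merged = observed.merge(random_coil, on="residue", suffixes=("", "_rc"))
    dropped = sorted(set(observed["residue"]) - set(merged["residue"]))
    raw = (merged["delta_CA"] - merged["delta_CA_rc"]) - (merged["delta_CB"] - merged["delta_CB_rc"])
    keep = raw.notna()
    if (~keep).any() or dropped:
        n_bad = int((~keep).sum()) + len(dropped)
        warnings.warn(f"{n_bad} residue(s) excluded from secondary shifts (missing Cα/Cβ)")
    resid = merged.loc[keep, "residue"].to_numpy(int)
    vals = dict(zip(resid, raw[keep].to_numpy(float)))
    smoothed = []
    for r in resid:
        w, s = 2.0, 2.0 * vals[r]
        for nb in (r - 1, r + 1):
            if nb in vals:
                w += 1.0
                s += vals[nb]
        smoothed.append(s / w)
    return pd.DataFrame({"residue": resid, "raw": [vals[r] for r in resid], "smoothed": smoothed})


def rotamer_population(probe: ProbeID | str, delta_obs: float, atom_label: str | None = None) -> dict:
    """Population of the trans rotamer from an Ile-δ1 or Met-ε 13C shift.

    Inverts the linear calibration; values outside [0, 1] are clamped with a
    warning (real shifts can exceed the calibration endpoints).  Returns a dict
    with ``p_trans`` and ``rotamer_class`` in {trans, gauche_minus, mixed}.
    """
    label = atom_label or (probe.atom_label if isinstance(probe, ProbeID) else str(probe))
    if label not in ROTAMER_CALIBRATIONS:
        raise TypeError(
            f"rotamer populations are defined for Ile-d1 and Met-e probes only, got {label!r}"
        )
    intercept, slope = ROTAMER_CALIBRATIONS[label]
    p = (float(delta_obs) - intercept) / slope
    if not 0.0 <= p <= 1.0:
        warnings.warn(
            f"p_trans {p:.3f} outside [0,1] for {probe} (shift outside calibration range); clamped"
        )
        p = min(1.0, max(0.0, p))
    if p >= 0.75:
        klass = "trans"
    elif p <= 0.25:
        klass = "gauche_minus"
    else:
        klass = "mixed"
    return {"probe": probe, "p_trans": p, "rotamer_class": klass}


def rotamer_delta(holo: pd.DataFrame, apo: pd.DataFrame) -> pd.DataFrame:
    """Per-probe change in p_trans between holo and apo states.

    Δ = p_trans(holo) − p_trans(apo); positive means a move toward *trans*.
    Probes present in only one table are excluded and listed in ``attrs``.
    """
    merged = holo.merge(apo, on="probe", suffixes=("_holo", "_apo"))
    if merged.empty:
        raise EmptyOverlapError("no probes shared between holo and apo rotamer tables")
    delta = merged["p_trans_holo"] - merged["p_trans_apo"]
    out = pd.DataFrame(
        {
            "probe": merged["probe"],
            "delta_p_trans": delta,
            "direction": np.where(
                delta > 0, "toward_trans", np.where(delta < 0, "toward_gauche_minus", "unchanged")
            ),
        }
    )
    out.attrs["holo_only"] = sorted(set(holo["probe"]) - set(apo["probe"]))
    out.attrs["apo_only"] = sorted(set(apo["probe"]) - set(holo["probe"]))
    return out


def build_noe_network(crosspeaks: pd.DataFrame) -> nx.Graph:
    """Symmetric simple graph of methyl-methyl NOE contacts.

    ``crosspeaks`` columns: ``probe_a, probe_b`` and optionally ``intensity``.
    Reciprocal peaks collapse onto one edge (count accumulated, intensity
    averaged); self-pairs are dropped with a warning.
    """
    g = nx.Graph()
    n_self = 0
    for row in crosspeaks.itertuples(index=False):
        a, b = row.probe_a, row.probe_b
        if a == b:
            n_self += 1
            continue
        inten = float(getattr(row, "intensity", np.nan))
        if g.has_edge(a, b):
            e = g.edges[a, b]
            e["count"] += 1
            if not np.isnan(inten):
                e["mean_intensity"] = (
                    (e["mean_intensity"] * (e["count"] - 1) + inten) / e["count"]
                    if not np.isnan(e["mean_intensity"])
                    else inten
                )
        else:
            g.add_edge(a, b, count=1, mean_intensity=inten)
    if n_self:
        warnings.warn(f"dropped {n_self} self-pair row(s) from NOE cross-peak list")
    return g


def diff_noe_networks(a: nx.Graph, b: nx.Graph) -> dict:
    """Edge-identity difference between two NOE networks.

    Returns ``{"gained": ..., "lost": ..., "retained": ...}`` as sets of
    frozen probe pairs, relative to going from network ``a`` to network ``b``.
    """
    ea = {frozenset(e) for e in a.edges}
    eb = {frozenset(e) for e in b.edges}
    return {"gained": eb - ea, "lost": ea - eb, "retained": ea & eb}
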