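"""Slow-exchange NMR thermodynamics of proline cis/trans isomerization.

In the slow-exchange regime the cis and trans isomers give separate peaks
whose volumes are proportional to the state concentrations, so per-residue
populations follow directly from peak quantification.  The temperature
dependence of the equilibrium constant K = [cis]/[trans] yields the
isomerization enthalpy and entropy by van 't Hoff regression of ln K on
1/T (dH = -R * slope, dS = R * intercept), from which the cis population at
any temperature can be predicted.

The module also covers three chemical-shift diagnostics for disordered
peptides: amide-proton temperature coefficients (slopes more negative than
-4.5 ppb/K indicate the amide is not in a persistent hydrogen bond), the
proline 13C beta-gamma shift difference (~9.5 ppm for cis, ~4.5 ppm for
trans), and a secondary-structure-propensity (SSP) score computed from
1Ha/13Ca/13Cb secondary shifts against a random-coil reference table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT",
    "CisPopulation",
    "ThermoFit",
    "TempCoefficient",
    "cis_population",
    "equilibrium_constant",
    "population_from_k",
    "vant_hoff_fit",
    "population_at_temperature",
    "temperature_coefficient",
    "proline_isomer_from_shifts",
    "load_random_coil_table",
    "ssp_score",
]

#: molar gas constant, J K^-1 mol^-1
GAS_CONSTANT = 8.314

HBOND_COEFF_THRESHOLD = -4.5   # ppb/K


@dataclass
class CisPopulation:
    mean: float                     # fraction in [0, 1]
    sd: float                       # sample SD across residues
    per_residue: dict
    excluded: list


@dataclass
class ThermoFit:
    delta_h: float                  # J/mol
    delta_h_se: float
    delta_s: float                  # J/(K mol)
    delta_s_se: float
    residuals: np.ndarray           # ln K residuals
    n_temperatures: int


@dataclass
class TempCoefficient:
    slope_ppb_per_k: float
    slope_se: float
    hbond_flag: str                 # "no persistent H-bond" or "possible H-bond"


def cis_population(table: pd.DataFrame, statistic: str = "volume",
                   residues=None) -> CisPopulation:
    """Mean cis population across residues from a peak-quantification table.

    ``table`` needs columns residue / isomer / <statistic>; per residue
    p = V_cis / (V_cis + V_trans).  Residues missing either isomer peak are
    excluded and reported.  The aggregate is the mean and sample SD (ddof=1)
    across the remaining residues.
    """
    if statistic not in table.columns:
        raise ValueError(f"table has no column {statistic!r}")
    wanted = residues if residues is not None else sorted(table["residue"].unique())
    per_res, excluded = {}, []
    for res in wanted:
        sub = table[table["residue"] == res]
        vc = sub.loc[sub["isomer"] == "cis", statistic]
        vt = sub.loc[sub["isomer"] == "trans", statistic]
        if len(vc) != 1 or len(vt) != 1:
            excluded.append(res)
            continue
        per_res[res] = float(vc.iloc[0] / (vc.iloc[0] + vt.iloc[0]))
    if not per_res:
        raise ValueError("no residue has both isomer peaks")
    vals = np.array(list(per_res.values()))
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return CisPopulation(float(vals.mean()), sd, per_res, excluded)


def equilibrium_constant(p_cis: float) -> float:
    """K = [cis]/[trans] = p / (1 - p) for p strictly inside (0, 1)."""
    if not 0.0 < p_cis < 1.0:
        raise ValueError("cis population must lie strictly in (0, 1)")
    return p_cis / (1.0 - p_cis)


def population_from_k(k: float) -> float:
    """Inverse of :func:`equilibrium_constant`: p = K / (1 + K)."""
    if k <= 0:
        raise ValueError("equilibrium constant must be positive")
    return k / (1.0 + k)


def _wls_line(x, y, sigma=None):
    """Weighted least-squares line y = slope*x + intercept.

    With sigma given the parameter covariance is the unscaled
    (X^T W X)^{-1}; otherwise it is scaled by the residual variance.
    Returns slope, intercept, se_slope, se_intercept, residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.stack([x, np.ones_like(x)], axis=1)
    if sigma is not None:
        sig = np.asarray(sigma, dtype=float)
        w = 1.0 / sig
    else:
        w = np.ones_like(x)
    aw = design * w[:, None]
    bw = y * w
    coef, *_ = np.linalg.lstsq(aw, bw, rcond=None)
    cov = np.linalg.inv(aw.T @ aw)
    resid = y - design @ coef
    if sigma is None:
        dof = max(len(x) - 2, 1)
        cov = cov * float(np.sum(resid ** 2) / dof)
    return coef[0], coef[1], np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1]), resid


def vant_hoff_fit(temperatures, k_values, lnk_sigma=None) -> ThermoFit:
    """van 't Hoff regression of ln K on 1/T.

    dH = -R * slope (J/mol) and dS = R * intercept (J/(K mol)); standard
    errors come from the regression covariance (unscaled when per-point
    ln-K uncertainties are supplied, residual-scaled otherwise).
    """
    t = np.asarray(temperatures, dtype=float)
    k = np.asarray(k_values, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 temperatures")
    if np.any(t <= 0) or np.any(k <= 0):
        raise ValueError("temperatures and K values must be positive")
    slope, intercept, se_s, se_i, resid = _wls_line(1.0 / t, np.log(k),
                                                    lnk_sigma)
    return ThermoFit(
        delta_h=-GAS_CONSTANT * slope,
        delta_h_se=GAS_CONSTANT * se_s,
        delta_s=GAS_CONSTANT * intercept,
        delta_s_se=GAS_CONSTANT * se_i,
        residuals=resid,
        n_temperatures=len(t),
    )


def population_at_temperature(delta_h: float, delta_s: float,
                              temperature: float) -> float:
    """Predicted cis population p = K/(1+K), K = exp(-(dH - T dS)/(R T)).

    ``delta_h`` in J/mol, ``delta_s`` in J/(K mol), temperature in kelvin.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    k = np.exp(-(delta_h - temperature * delta_s)
               / (GAS_CONSTANT * temperature))
    return float(k / (1.0 + k))


def temperature_coefficient(temperatures, shifts_ppm) -> TempCoefficient:
    """Amide-proton temperature coefficient in ppb/K by least squares.

    Slopes more negative than -4.5 ppb/K flag the amide as free of a
    persistent intramolecular hydrogen bond.
    """
    t = np.asarray(temperatures, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 temperatures")
    slope, _, se, _, _ = _wls_line(t, np.asarray(shifts_ppm, dtype=float))
    slope_ppb = slope * 1e3
    flag = ("no persistent H-bond" if slope_ppb < HBOND_COEFF_THRESHOLD
            else "possible H-bond")
    return TempCoefficient(float(slope_ppb), float(se * 1e3), flag)


def proline_isomer_from_shifts(delta_cb: float, delta_cg: float,
                               cis_min: float = 8.0,
                               trans_max: float = 6.0) -> str:
    """Proline isomer from the 13C beta-gamma shift difference.

    The difference is ~9.5 ppm for cis-proline and ~4.5 ppm for trans;
    values between ``trans_max`` and ``cis_min`` are reported ambiguous.
    """
    d = delta_cb - delta_cg
    if not np.isfinite(d):
        raise ValueError("shifts must be finite")
    if d >= cis_min:
        return "cis"
    if d <= trans_max:
        return "trans"
    return "ambiguous"


def load_random_coil_table() -> pd.DataFrame:
    """Shipped random-coil and secondary-shift reference table.

    Columns: residue (one-letter), nucleus (CA/CB/HA), coil_shift,
    alpha_secondary, beta_secondary (ppm).  Users may edit or replace it;
    the reference set materially affects SSP scores.
    """
    ref = importlib.resources.files("prolens") / "data" / "random_coil_shifts.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def ssp_score(observed: pd.DataFrame, sequence: str,
              reference: pd.DataFrame | None = None,
              window: int = 5) -> pd.Series:
    """Secondary-structure propensity score per residue, in [-1, 1].

    ``observed`` needs columns residue_id (1-based), nucleus (CA/CB/HA) and
    shift (ppm).  Secondary shifts (observed minus random coil) are averaged
    over a centred, end-truncated window of ``window`` residues, with each
    nucleus oriented by the sign of its helix reference shift; the result is
    normalized by the helix reference magnitude when positive and by the
    strand reference magnitude when negative, then capped to [-1, 1].
    +1 reads full helix, -1 full strand, 0 random coil.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    ref = reference if reference is not None else load_random_coil_table()
    ref_ix = ref.set_index(["residue", "nucleus"])
    n = len(sequence)
    half = window // 2

    # per (residue, nucleus): oriented secondary shift and reference magnitudes
    sec, mag_a, mag_b = {}, {}, {}
    for _, row in observed.iterrows():
        rid = int(row["residue_id"])
        nuc = str(row["nucleus"])
        aa = sequence[rid - 1]
        try:
            r = ref_ix.loc[(aa, nuc)]
        except KeyError:
            continue   # nucleus missing from the reference: skip
        sign = 1.0 if r["alpha_secondary"] >= 0 else -1.0
        sec.setdefault(rid, []).append((row["shift"] - r["coil_shift"]) * sign)
        mag_a.setdefault(rid, []).append(abs(r["alpha_secondary"]))
        mag_b.setdefault(rid, []).append(abs(r["beta_secondary"]))

    scores = {}
    for rid in range(1, n + 1):
        win = [j for j in range(max(1, rid - half), min(n, rid + half) + 1)
               if j in sec]
        if not win:
            scores[rid] = np.nan
            continue
        s = sum(v for j in win for v in sec[j])
        d_a = sum(v for j in win for v in mag_a[j])
        d_b = sum(v for j in win for v in mag_b[j])
        raw = s / d_a if s >= 0 else s / d_b
        scores[rid] = float(np.clip(raw, -1.0, 1.0))
    return pd.Series(scores, name="ssp")
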