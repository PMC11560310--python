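"""SAXS and hydrodynamic forward models for conformer ensembles.

Scattering curves are computed with the Debye formula over one effective
scattering centre per residue (the Calpha position, unit form factor by
default); this is a coarse but internally consistent substitute for
atomic-detail predictors, adequate for driving and testing ensemble
reweighting.  The module also provides Guinier analysis of low-q profiles,
least-squares scale/offset fitting of calculated against experimental
curves, the Kirkwood hydrodynamic-radius approximation, and the
Stokes-Einstein translational diffusion coefficient.

Units: q in nm^-1, distances in nm, D in m^2/s, viscosity in Pa s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BOLTZMANN",
    "SAXSProfile",
    "GuinierResult",
    "HydrodynamicResult",
    "saxs_debye",
    "ensemble_saxs",
    "per_frame_saxs",
    "guinier_fit",
    "fit_scale_offset",
    "kirkwood_rh",
    "ensemble_rh",
    "stokes_einstein_d",
    "hydrodynamics",
]

#: Boltzmann constant, J/K
BOLTZMANN = 1.380649e-23

#: water viscosity at 288.15 K (15 degC), Pa s
WATER_VISCOSITY_288K = 1.138e-3


@dataclass
class SAXSProfile:
    """A scattering profile: momentum transfer q (nm^-1), intensity, and
    optional 1-sigma uncertainties (same arbitrary units as I)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    error_rescale: float = 1.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.q < 0):
            raise ValueError("q must be nonnegative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q grid")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    @property
    def effective_sigma(self) -> np.ndarray:
        if self.sigma is None:
            raise ValueError("profile carries no uncertainties")
        return self.sigma * self.error_rescale

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class GuinierResult:
    rg: float                 # nm
    i0: float
    q_window: tuple[float, float]
    n_points: int
    r_squared: float


@dataclass
class HydrodynamicResult:
    rh: float                 # nm
    diffusion: float          # m^2/s
    temperature: float        # K
    viscosity: float          # Pa s


def _debye_single(centers: np.ndarray, f: np.ndarray, q: np.ndarray) -> np.ndarray:
    n = len(centers)
    ii, jj = np.triu_indices(n, k=1)
    r = np.linalg.norm(centers[ii] - centers[jj], axis=-1)
    ff = f[ii] * f[jj]
    self_term = np.sum(f ** 2)
    out = np.empty(len(q))
    for k, qk in enumerate(q):   # one q at a time keeps memory O(n^2)
        qr = qk * r
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 0, qr, 1.0),
                            1.0)
        out[k] = self_term + 2.0 * np.dot(ff, sinc)
    return out


def saxs_debye(centers_or_conformer, q, form_factors=None) -> SAXSProfile:
    """Debye-formula scattering curve of one frame.

    ``centers_or_conformer`` is either an (n, 3) array of scattering-centre
    coordinates in nm or a Conformer (whose Calpha atoms are used).
    I(q) = sum_ij f_i f_j sin(q r_ij)/(q r_ij), with the q r -> 0 limit
    f_i f_j, so I(0) = (sum f)^2.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if q.size == 0:
        raise ValueError("q grid must be nonempty")
    centers = _as_centers(centers_or_conformer)
    f = (np.ones(len(centers)) if form_factors is None
         else np.asarray(form_factors, dtype=float))
    if np.any(f <= 0):
        raise ValueError("form factors must be positive")
    return SAXSProfile(q, _debye_single(centers, f, q))


def _as_centers(obj) -> np.ndarray:
    if hasattr(obj, "atom_names"):  # Conformer
        return obj.coords[obj.atom_names == "CA"]
    return np.asarray(obj, dtype=float)


def per_frame_saxs(ensemble, q, form_factors=None) -> np.ndarray:
    """Per-frame Debye intensities, shape (n_frames, n_q)."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    ca = ensemble.ca_coords()
    f = (np.ones(ca.shape[1]) if form_factors is None
         else np.asarray(form_factors, dtype=float))
    out = np.empty((ca.shape[0], q.size))
    for i in range(ca.shape[0]):
        out[i] = _debye_single(ca[i], f, q)
    return out


def ensemble_saxs(ensemble, q, form_factors=None,
                  weights=None) -> SAXSProfile:
    """Weight-averaged Debye profile of an ensemble."""
    w = ensemble.weights if weights is None else np.asarray(weights, float)
    intens = per_frame_saxs(ensemble, q, form_factors)
    return SAXSProfile(np.atleast_1d(np.asarray(q, float)), w @ intens)


def guinier_fit(profile: SAXSProfile, q_rg_limit: float = 1.3,
                n_iter: int = 2) -> GuinierResult:
    """Guinier analysis: weighted regression of ln I on q^2 at low q.

    The fit window satisfies q * Rg <= ``q_rg_limit`` and is iterated to
    self-consistency (``n_iter`` refinements of the window from the current
    Rg estimate).  Rg = sqrt(-3 * slope).  A positive slope (no Guinier
    decay) raises ValueError.
    """
    q, i = profile.q, profile.intensity
    pos = i > 0
    mask = pos.copy()
    rg = None
    for _ in range(n_iter + 1):
        if mask.sum() < 5:
            raise ValueError("fewer than 5 points inside the Guinier window")
        x = q[mask] ** 2
        y = np.log(i[mask])
        if profile.sigma is not None:
            wts = (i[mask] / profile.effective_sigma[mask]) ** 2
        else:
            wts = np.ones_like(x)
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(wts))
        if slope > 0:
            raise ValueError("positive Guinier slope: Rg undefined")
        rg = float(np.sqrt(-3.0 * slope))
        if rg == 0.0:
            break
        mask = pos & (q * rg <= q_rg_limit)
    x = q[mask] ** 2
    y = np.log(i[mask])
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GuinierResult(rg=rg, i0=float(np.exp(intercept)),
                         q_window=(float(q[mask].min()), float(q[mask].max())),
                         n_points=int(mask.sum()), r_squared=r2)


def fit_scale_offset(calculated: SAXSProfile, experimental: SAXSProfile,
                     offset: bool = True):
    """Least-squares scale (and optional offset) of calculated onto
    experimental intensities.

    Minimizes sum_j ((I_exp - a I_calc - b) / sigma)^2 over (a, b); with
    ``offset=False`` b is pinned at 0.  The calculated profile is linearly
    interpolated onto the experimental q grid.  Returns (a, b, chi2_per_point).
    """
    q = experimental.q
    icalc = np.interp(q, calculated.q, calculated.intensity)
    iexp = experimental.intensity
    sig = (experimental.effective_sigma if experimental.sigma is not None
           else np.ones_like(iexp))
    if np.ptp(icalc) < 1e-14 * max(1.0, abs(icalc[0])):
        raise ValueError("degenerate (constant) calculated profile")
    if offset:
        design = np.stack([icalc, np.ones_like(icalc)], axis=1)
    else:
        design = icalc[:, None]
    aw = design / sig[:, None]
    bw = iexp / sig
    coef, *_ = np.linalg.lstsq(aw, bw, rcond=None)
    a = float(coef[0])
    b = float(coef[1]) if offset else 0.0
    resid = (iexp - a * icalc - b) / sig
    chi2 = float(np.sum(resid ** 2) / len(q))
    return a, b, chi2


def kirkwood_rh(centers_or_conformer) -> float:
    """Kirkwood hydrodynamic radius of one frame (nm).

    Rh^-1 = (1/N^2) * sum_{i != j} r_ij^-1 over scattering centres.
    """
    centers = _as_centers(centers_or_conformer)
    n = len(centers)
    if n < 2:
        raise ValueError("need at least 2 centres")
    r = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < 1e-12):
        raise ValueError("coincident centres give an infinite Kirkwood term")
    inv = np.sum(1.0 / r[off]) / n ** 2
    return float(1.0 / inv)


def ensemble_rh(ensemble, weights=None) -> float:
    """Ensemble hydrodynamic radius: harmonic (mobility) average of 1/Rh.

    Fast exchange within a subensemble averages diffusion coefficients,
    i.e. 1/Rh, so Rh_ens = 1 / <1/Rh>_w.
    """
    w = ensemble.weights if weights is None else np.asarray(weights, float)
    ca = ensemble.ca_coords()
    inv = np.empty(len(ca))
    for i in range(len(ca)):
        inv[i] = 1.0 / kirkwood_rh(ca[i])
    return float(1.0 / np.dot(w, inv))


def stokes_einstein_d(rh_nm: float, temperature: float = 288.15,
                      viscosity: float = WATER_VISCOSITY_288K) -> float:
    """Stokes-Einstein diffusion coefficient D = kB T / (6 pi eta Rh), m^2/s."""
    if rh_nm <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("inputs must be positive")
    return BOLTZMANN * temperature / (6.0 * np.pi * viscosity * rh_nm * 1e-9)


def hydrodynamics(ensemble, temperature: float = 288.15,
                  viscosity: float = WATER_VISCOSITY_288K) -> HydrodynamicResult:
    rh = ensemble_rh(ensemble)
    return HydrodynamicResult(rh=rh,
                              diffusion=stokes_einstein_d(rh, temperature, viscosity),
                              temperature=temperature, viscosity=viscosity)
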