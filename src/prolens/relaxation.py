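"""15N spin relaxation and NMR diffusion analysis.

Relaxation rates are extracted from intensity decays by monoexponential
fitting; R2 is reconstructed from R1 and the rotating-frame rate R1rho via
the tilt angle of the effective spin-lock field; the steady-state {1H}-15N
NOE is an intensity ratio with propagated noise.  Reduced spectral density
mapping converts (R1, R2, NOE) at one static field into the spectral
density at three frequencies — J(0), J(wN) and an effective high-frequency
value J(0.87 wH) — under the standard approximation that J varies slowly
near the proton frequency.  An exchange-free transverse rate (R_dd) allows
microsecond-millisecond exchange contributions Rex = R2 - kappa R_dd to be
isolated.  Translational diffusion follows from Stejskal-Tanner fits of
pulsed-field-gradient decays, with subensemble comparisons by a one-tailed
Welch t-test.

Dipolar and CSA interaction constants follow the convention
d = (mu0/4pi) hbar gammaH gammaN / r_NH^3 and c = wN * dCSA / sqrt(3), with

    R1    = (d^2/4) [3J(wN) + J(wH-wN) + 6J(wH+wN)] + c^2 J(wN)
    R2    = (d^2/8) [4J(0) + 3J(wN) + J(wH-wN) + 6J(wH) + 6J(wH+wN)]
            + (c^2/6) [4J(0) + 3J(wN)]
    sigma = (d^2/4) [6J(wH+wN) - J(wH-wN)],  NOE = 1 + (gH/gN) sigma/R1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "RelaxationConstants",
    "SpectralDensities",
    "DiffusionFit",
    "fit_monoexponential",
    "r2_from_r1rho",
    "hetnoe",
    "lorentzian_j",
    "forward_relaxation_rates",
    "reduced_spectral_density",
    "exchange_contribution",
    "stejskal_tanner_fit",
    "welch_t_one_tailed",
    "montecarlo_errors",
]

MU0 = 4e-7 * np.pi            # T m / A
HBAR = 1.054571817e-34        # J s
GAMMA_H = 2.6752218744e8      # rad s^-1 T^-1
GAMMA_N = -2.7116e7           # rad s^-1 T^-1 (15N, negative)


@dataclass(frozen=True)
class RelaxationConstants:
    """Field and interaction constants for 15N backbone relaxation.

    Defaults: 14.1 T, r_NH = 1.02 Angstrom, 15N CSA = -160 ppm.
    """

    b0: float = 14.1                    # T
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N
    r_nh: float = 1.02e-10              # m
    csa: float = -160e-6                # dimensionless (ppm * 1e-6)

    @property
    def omega_h(self) -> float:
        return abs(self.gamma_h) * self.b0

    @property
    def omega_n(self) -> float:
        return abs(self.gamma_n) * self.b0

    @property
    def d(self) -> float:
        """Dipolar constant (rad/s)."""
        return (MU0 / (4 * np.pi)) * HBAR * abs(self.gamma_h) * \
            abs(self.gamma_n) / self.r_nh ** 3

    @property
    def c(self) -> float:
        """CSA constant (rad/s): wN * dCSA / sqrt(3)."""
        return self.omega_n * abs(self.csa) / np.sqrt(3.0)


@dataclass
class SpectralDensities:
    j0: float                   # s/rad
    j_wn: float
    j_wh_eff: float             # J(0.87 wH)
    j0_se: float = np.nan
    j_wn_se: float = np.nan
    j_wh_eff_se: float = np.nan


@dataclass
class DiffusionFit:
    diffusion: float            # m^2/s
    diffusion_se: float
    i0: float


def fit_monoexponential(delays, intensities, sigma=None):
    """Fit I(t) = I0 exp(-R t) by nonlinear least squares.

    Returns (rate, rate_se).  A non-decaying series yields a nonpositive
    rate (reported, not raised) so callers can flag it.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 delays")
    # log-linear initialization where intensities are positive
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (float(y[0]), 1.0 / max(t[-1], 1e-12))

    def model(tt, i0, r):
        return i0 * np.exp(-r * tt)

    popt, pcov = curve_fit(model, t, y, p0=p0, sigma=sigma,
                           absolute_sigma=sigma is not None, maxfev=10000)
    return float(popt[1]), float(np.sqrt(pcov[1, 1]))


def r2_from_r1rho(r1rho: float, r1: float, tilt_deg: float,
                  r1rho_se: float = 0.0, r1_se: float = 0.0):
    """R2 = (R1rho - R1 cos^2 theta) / sin^2 theta with quadrature SE.

    ``tilt_deg`` is the angle between the effective spin-lock field and the
    static field, in (0, 90].
    """
    th = np.radians(tilt_deg)
    s2 = np.sin(th) ** 2
    if s2 < 1e-6:
        raise ValueError("tilt angle too small: sin^2(theta) < 1e-6")
    c2 = np.cos(th) ** 2
    r2 = (r1rho - r1 * c2) / s2
    se = np.sqrt((r1rho_se / s2) ** 2 + (r1_se * c2 / s2) ** 2)
    return float(r2), float(se)


def hetnoe(i_saturated: float, i_reference: float,
           sd_saturated: float = 0.0, sd_reference: float = 0.0):
    """Steady-state heteronuclear NOE = I_sat / I_ref with first-order SE."""
    if i_reference == 0:
        raise ValueError("reference intensity must be nonzero")
    ratio = i_saturated / i_reference
    # first-order propagation, valid also at I_sat = 0
    se = np.sqrt((sd_saturated / i_reference) ** 2
                 + (ratio * sd_reference / i_reference) ** 2)
    return float(ratio), float(se)


def lorentzian_j(tau_c: float):
    """Single-Lorentzian spectral density J(w) = (2/5) tau_c / (1 + (w tau_c)^2)."""
    def j(omega):
        return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)
    return j


def forward_relaxation_rates(j, constants: RelaxationConstants):
    """(R1, R2, NOE) from a spectral density function at the stated field."""
    k = constants
    d2 = k.d ** 2
    c2 = k.c ** 2
    wh, wn = k.omega_h, k.omega_n
    r1 = (d2 / 4) * (3 * j(wn) + j(wh - wn) + 6 * j(wh + wn)) + c2 * j(wn)
    r2 = (d2 / 8) * (4 * j(0.0) + 3 * j(wn) + j(wh - wn)
                     + 6 * j(wh) + 6 * j(wh + wn)) \
        + (c2 / 6) * (4 * j(0.0) + 3 * j(wn))
    sigma = (d2 / 4) * (6 * j(wh + wn) - j(wh - wn))
    noe = 1.0 + (k.gamma_h / k.gamma_n) * sigma / r1
    return float(r1), float(r2), float(noe)


def reduced_spectral_density(r1: float, r2: float, noe: float,
                             constants: RelaxationConstants,
                             r1_se: float = 0.0, r2_se: float = 0.0,
                             noe_se: float = 0.0) -> SpectralDensities:
    """Map (R1, R2, NOE) at one field to J(0), J(wN), J(0.87 wH).

    Uses the high-frequency approximation J(wH-wN) ~ J(wH) ~ J(wH+wN) ~
    J(0.87 wH):

        sigma        = R1 (NOE - 1) gammaN/gammaH
        J(0.87 wH)   = 4 sigma / (5 d^2)
        J(wN)        = (R1 - 7 (d^2/4) J(0.87 wH)) / (3 d^2/4 + c^2)
        J(0)         = (R2 - 13 (d^2/8) J(0.87wH) - (3 d^2/8 + c^2/2) J(wN))
                       / (d^2/2 + 2 c^2/3)

    Standard errors propagate linearly through the same map.
    """
    k = constants
    d2 = k.d ** 2
    c2 = k.c ** 2

    def _map(r1v, r2v, noev):
        sigma = r1v * (noev - 1.0) * (k.gamma_n / k.gamma_h)
        j_hf = 4.0 * sigma / (5.0 * d2)
        j_wn = (r1v - 7.0 * (d2 / 4.0) * j_hf) / (0.75 * d2 + c2)
        j_0 = (r2v - (13.0 * d2 / 8.0) * j_hf
               - (3.0 * d2 / 8.0 + c2 / 2.0) * j_wn) / (d2 / 2.0 + 2.0 * c2 / 3.0)
        return j_0, j_wn, j_hf

    j_0, j_wn, j_hf = _map(r1, r2, noe)
    # linear error propagation by finite differences of the analytic map
    ses = np.zeros(3)
    for dv, i in ((r1_se, 0), (r2_se, 1), (noe_se, 2)):
        if dv == 0:
            continue
        args = [r1, r2, noe]
        args[i] += dv
        pert = _map(*args)
        ses += (np.array(pert) - np.array([j_0, j_wn, j_hf])) ** 2
    se0, sewn, sehf = np.sqrt(ses)
    return SpectralDensities(j_0, j_wn, j_hf, se0, sewn, sehf)


def exchange_contribution(r2: float, r_dd: float, kappa: float = 1.0,
                          r2_se: float = 0.0, r_dd_se: float = 0.0):
    """Rex = R2 - kappa * R_dd with quadrature SE and a no-exchange flag.

    ``kappa`` rescales the exchange-free rate to the R2 field/conditions.
    Returns (rex, se, flag) where flag is True when |Rex| < 2 SE
    (no detectable exchange).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rex = r2 - kappa * r_dd
    se = np.sqrt(r2_se ** 2 + (kappa * r_dd_se) ** 2)
    return float(rex), float(se), bool(abs(rex) < 2.0 * se)


def stejskal_tanner_fit(gradients, intensities, delta: float,
                        big_delta: float,
                        gamma: float = GAMMA_H) -> DiffusionFit:
    """Fit I(g) = I0 exp(-D gamma^2 g^2 delta^2 (Delta - delta/3)).

    ``gradients`` in T/m (nonnegative, increasing), ``delta`` (gradient
    pulse) and ``big_delta`` (diffusion delay) in s.  D in m^2/s with SE
    from the fit covariance.
    """
    g = np.asarray(gradients, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(g) < 4:
        raise ValueError("need at least 4 gradient points")
    if np.any(g < 0) or np.any(np.diff(g) <= 0):
        raise ValueError("gradients must be nonnegative and increasing")
    if big_delta <= delta / 3.0:
        raise ValueError("diffusion delay must exceed delta/3")
    b = (gamma * g * delta) ** 2 * (big_delta - delta / 3.0)

    pos = y > 0
    if pos.sum() >= 2 and np.ptp(b[pos]) > 0:
        slope, intercept = np.polyfit(b[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(max(-slope, 0.0)))
    else:
        p0 = (float(y[0]), 1e-10)

    def model(bb, i0, dd):
        return i0 * np.exp(-dd * bb)

    popt, pcov = curve_fit(model, b, y, p0=p0, maxfev=10000)
    return DiffusionFit(float(popt[1]), float(np.sqrt(pcov[1, 1])),
                        float(popt[0]))


def welch_t_one_tailed(mean1, sd1, n1, mean2, sd2, n2,
                       direction: str = "greater"):
    """One-tailed Welch t-test from summary statistics.

    ``direction='greater'`` tests mean1 > mean2; ``'less'`` tests
    mean1 < mean2.  Returns (t, df, p) with the Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    if direction == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return float(t), float(df), float(p)


def montecarlo_errors(fit_func, data: np.ndarray, uncertainties: np.ndarray,
                      n_draws: int = 1000, seed: int = 0) -> np.ndarray:
    """Monte Carlo uncertainty propagation for an arbitrary fit.

    ``fit_func`` maps a data vector to parameter(s); ``uncertainties`` are
    per-point Gaussian SDs.  Returns the SD of the refit parameters over
    ``n_draws`` resamples (seeded, reproducible).
    """
    if n_draws < 100:
        raise ValueError("need at least 100 draws")
    rng = np.random.default_rng(seed)
    data = np.asarray(data, dtype=float)
    unc = np.broadcast_to(np.asarray(uncertainties, dtype=float), data.shape)
    results = []
    for _ in range(n_draws):
        perturbed = data + rng.normal(0.0, 1.0, size=data.shape) * unc
        results.append(np.atleast_1d(np.asarray(fit_func(perturbed), float)))
    return np.asarray(results).std(axis=0, ddof=1)
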