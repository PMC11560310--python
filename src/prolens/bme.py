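"""Bayesian/maximum-entropy (BME) reweighting of conformer ensembles.

Given prior frame weights w0 and experimental restraints (observed values
o_j with uncertainties sigma_j, plus the per-frame calculated observables
F[i, j]), BME finds posterior weights

    w_i(lambda) = w0_i * exp(-sum_j lambda_j F_ij) / Z(lambda)

where the Lagrange multipliers minimize the convex dual

    Gamma(lambda) = ln Z(lambda) + sum_j lambda_j o_j
                    + (theta/2) * sum_j lambda_j^2 sigma_j^2.

theta balances goodness of fit against the relative-entropy cost of moving
away from the prior; theta -> infinity returns the prior, theta -> 0
enforces the restraints exactly (in the limit of compatible data).  The
effective retained ensemble fraction is phi_eff = exp(S_rel) with
S_rel = -sum_i w_i ln(w_i / w0_i).

For SAXS restraints, :func:`reweight_saxs` alternates the scale/offset fit
of the calculated curve against the experimental one with multiplier
updates, as is standard when the experimental intensity scale is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .scattering import SAXSProfile, fit_scale_offset, per_frame_saxs

__all__ = [
    "RestraintSet",
    "BMEResult",
    "chi2",
    "fit_bme",
    "theta_scan",
    "reweight_saxs",
]


@dataclass
class RestraintSet:
    """Experimental restraints plus the per-frame calculated observables."""

    labels: list
    observed: np.ndarray        # (m,)
    sigma: np.ndarray           # (m,)
    calculated: np.ndarray      # (n_frames, m)

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.calculated = np.asarray(self.calculated, dtype=float)
        m = len(self.observed)
        if self.sigma.shape != (m,) or np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive, one per restraint")
        if self.calculated.ndim != 2 or self.calculated.shape[1] != m:
            raise ValueError("calculated must be (n_frames, n_restraints)")
        if not np.all(np.isfinite(self.calculated)):
            raise ValueError("calculated observables must be finite")

    @property
    def n_frames(self) -> int:
        return self.calculated.shape[0]

    @property
    def n_restraints(self) -> int:
        return len(self.observed)


@dataclass
class BMEResult:
    lambdas: np.ndarray
    weights: np.ndarray
    chi2_prior: float
    chi2_posterior: float
    s_rel: float
    phi_eff: float
    theta: float
    converged: bool
    grad_norm: float


def chi2(weights: np.ndarray, restraints: RestraintSet) -> float:
    """Reduced-sum goodness of fit: sum_j ((<F_j>_w - o_j)/sigma_j)^2."""
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be normalized")
    avg = w @ restraints.calculated
    return float(np.sum(((avg - restraints.observed) / restraints.sigma) ** 2))


def _posterior(w0_log, f, lambdas):
    logw = w0_log - f @ lambdas
    logw -= logsumexp(logw)
    return np.exp(logw)


def fit_bme(prior_weights: np.ndarray, restraints: RestraintSet,
            theta: float, gtol: float = 1e-10,
            maxiter: int = 2000) -> BMEResult:
    """Minimize the BME dual and return posterior weights and diagnostics.

    Quasi-Newton (L-BFGS-B) from lambda = 0 with the analytic gradient
    dGamma/dlambda_j = -<F_j>_w + o_j + theta lambda_j sigma_j^2.  The
    problem is convex, so the minimizer is unique; ``converged`` reports
    whether the gradient norm fell below 1e-8.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    w0 = np.asarray(prior_weights, dtype=float)
    if np.any(w0 < 0) or abs(w0.sum() - 1.0) > 1e-9:
        raise ValueError("prior weights must be normalized and nonnegative")
    if len(w0) != restraints.n_frames:
        raise ValueError("prior length must equal the number of frames")
    f = restraints.calculated
    o = restraints.observed
    sig2 = restraints.sigma ** 2
    with np.errstate(divide="ignore"):
        w0_log = np.where(w0 > 0, np.log(np.where(w0 > 0, w0, 1.0)), -np.inf)

    def gamma_and_grad(lam):
        logits = w0_log - f @ lam
        lz = logsumexp(logits)
        w = np.exp(logits - lz)
        g = lz + lam @ o + 0.5 * theta * np.sum(lam ** 2 * sig2)
        grad = -(w @ f) + o + theta * lam * sig2
        return g, grad

    res = minimize(gamma_and_grad, np.zeros(restraints.n_restraints),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-15})
    lam = res.x
    _, grad = gamma_and_grad(lam)
    gnorm = float(np.max(np.abs(grad)))
    w = _posterior(w0_log, f, lam)
    # underflow hygiene
    w = np.where(w < 1e-300, 0.0, w)
    w /= w.sum()
    mask = w > 0
    s_rel = float(-np.sum(w[mask] * np.log(w[mask] / w0[mask])))
    return BMEResult(
        lambdas=lam,
        weights=w,
        chi2_prior=chi2(w0, restraints),
        chi2_posterior=chi2(w, restraints),
        s_rel=s_rel,
        phi_eff=float(np.exp(s_rel)),
        theta=theta,
        converged=gnorm < 1e-8,
        grad_norm=gnorm,
    )


def theta_scan(prior_weights: np.ndarray, restraints: RestraintSet,
               thetas) -> list[BMEResult]:
    """Fit BME over a sorted positive theta grid; errors in one fit are
    reported in that entry's ``converged`` flag and the scan continues."""
    thetas = np.asarray(thetas, dtype=float)
    if np.any(thetas <= 0) or np.any(np.diff(thetas) <= 0):
        raise ValueError("theta grid must be positive and sorted ascending")
    out = []
    for th in thetas:
        try:
            out.append(fit_bme(prior_weights, restraints, float(th)))
        except Exception:
            w0 = np.asarray(prior_weights, dtype=float)
            out.append(BMEResult(
                lambdas=np.zeros(restraints.n_restraints), weights=w0,
                chi2_prior=chi2(w0, restraints),
                chi2_posterior=chi2(w0, restraints),
                s_rel=0.0, phi_eff=1.0, theta=float(th),
                converged=False, grad_norm=np.inf))
    return out


def select_theta(scan: list[BMEResult], chi2_per_restraint: float = 1.2):
    """Elbow rule: largest theta whose posterior chi2 per restraint stays at
    or below ``chi2_per_restraint`` (minimal perturbation that still fits).
    Falls back to the smallest theta if none qualifies."""
    n = None
    best = None
    for r in scan:
        if not r.converged:
            continue
        n = len(r.lambdas)
        if r.chi2_posterior / n <= chi2_per_restraint:
            if best is None or r.theta > best.theta:
                best = r
    return best if best is not None else scan[0]


def reweight_saxs(ensemble, experimental: SAXSProfile, theta: float,
                  form_factors=None, n_rounds: int = 5) -> tuple[BMEResult, float, float]:
    """BME against a SAXS profile with alternating scale/offset refit.

    Per round, the weighted-average calculated curve is fitted to the
    experimental one by (scale a, offset b); restraints are then the
    transformed experimental intensities (I_exp - b)/a with uncertainties
    sigma/a, and multipliers are refit.  Returns the final BMEResult and the
    last (a, b).
    """
    if experimental.sigma is None:
        raise ValueError("experimental SAXS profile needs uncertainties")
    q = experimental.q
    fcalc = per_frame_saxs(ensemble, q, form_factors)
    w = ensemble.weights
    a, b = 1.0, 0.0
    result = None
    for _ in range(n_rounds):
        calc_avg = SAXSProfile(q, w @ fcalc)
        a, b, _ = fit_scale_offset(calc_avg, experimental)
        rs = RestraintSet(
            labels=[f"q={qi:.4g}" for qi in q],
            observed=(experimental.intensity - b) / a,
            sigma=experimental.effective_sigma / a,
            calculated=fcalc,
        )
        result = fit_bme(ensemble.weights, rs, theta)
        w = result.weights
    return result, a, b
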