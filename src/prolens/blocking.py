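"""Blocking analysis of weighted collective-variable series.

Enhanced-sampling trajectories are autocorrelated, so the naive standard
error of a CV average underestimates the true uncertainty.  Blocking
(Flyvbjerg-Petersen) partitions the series into contiguous blocks of
increasing size; the standard error of the block means rises until blocks
exceed the correlation time and then plateaus at the true SE.  Convergence
of a free-energy surface is declared when its standard error is flat in
block size.

Frames may carry unequal statistical weights; blocks are then characterized
by weighted block means with the block weight sums as block masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockingCurve",
    "FESEstimate",
    "blocking_error",
    "fes_error",
    "plateau_detect",
]


@dataclass
class BlockingCurve:
    block_sizes: np.ndarray     # frames per block
    se: np.ndarray              # SE of the weighted mean at each size
    n_blocks: np.ndarray        # number of blocks per size

    def __post_init__(self):
        self.block_sizes = np.asarray(self.block_sizes, dtype=int)
        self.se = np.asarray(self.se, dtype=float)
        self.n_blocks = np.asarray(self.n_blocks, dtype=int)
        if np.any(np.diff(self.block_sizes) <= 0):
            raise ValueError("block sizes must be increasing")
        if np.any(self.n_blocks < 2):
            raise ValueError("need at least 2 blocks per reported size")


@dataclass
class FESEstimate:
    bin_centers: np.ndarray     # CV units
    free_energy: np.ndarray     # kB T, minimum shifted to 0
    se: np.ndarray              # kB T; NaN where unavailable


def default_block_sizes(n: int) -> np.ndarray:
    """Powers of 2 (Flyvbjerg-Petersen ladder).

    The ladder stops while at least 64 blocks remain (or n/2 for short
    series): the variance of an SE estimate from K blocks scales like
    1/sqrt(2K), so sizes with fewer blocks produce estimates too noisy to
    diagnose a plateau.
    """
    cap = max(n // 64, 2) if n >= 4096 else n // 2
    sizes = []
    b = 1
    while b <= cap:
        sizes.append(b)
        b *= 2
    return np.asarray(sizes, dtype=int)


def _block_stats(series, weights, b):
    """Weighted block means and normalized block masses for block size b."""
    n = len(series)
    k = n // b
    x = series[: k * b].reshape(k, b)
    w = weights[: k * b].reshape(k, b)
    mass = w.sum(axis=1)
    means = (w * x).sum(axis=1) / mass
    return means, mass / mass.sum(), k


def blocking_error(series, weights=None, block_sizes=None) -> BlockingCurve:
    """Standard error of the weighted series mean versus block size.

    For each block size b the frames are split into contiguous blocks;
    SE^2 = K/(K-1) * sum_k wtilde_k^2 (m_k - mbar)^2 with block means m_k,
    normalized block masses wtilde_k, and mbar the weighted grand mean.
    For uniform weights this reduces to the textbook SE of the mean of the
    block means.  Sizes leaving fewer than 2 blocks are skipped.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n:
            raise ValueError("series and weights must have equal length")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be normalized")
    if block_sizes is None:
        block_sizes = default_block_sizes(n)
    sizes, ses, counts = [], [], []
    for b in np.asarray(block_sizes, dtype=int):
        if b > n // 2:
            continue   # fewer than 2 blocks: skip
        means, wt, k = _block_stats(x, w, b)
        mbar = wt @ means
        se2 = k / (k - 1) * np.sum(wt ** 2 * (means - mbar) ** 2)
        sizes.append(b)
        ses.append(np.sqrt(se2))
        counts.append(k)
    return BlockingCurve(np.asarray(sizes), np.asarray(ses), np.asarray(counts))


def fes_error(series, weights=None, bins=30, n_blocks: int = 4) -> FESEstimate:
    """Free-energy surface along a CV with block-derived standard errors.

    The full weighted histogram gives per-bin probabilities p and free
    energies F = -ln p (kB T units, shifted so min F = 0).  The series is
    split into ``n_blocks`` contiguous blocks; the spread of the per-block
    probabilities gives SE_p, propagated to SE_F = SE_p / p.  Bins empty in
    any block report SE = NaN (unavailable, not zero).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
    edges = np.histogram_bin_edges(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p_full, _ = np.histogram(x, bins=edges, weights=w)
    p_full = p_full / p_full.sum()
    with np.errstate(divide="ignore"):
        fe = -np.log(p_full)
    fe -= np.nanmin(fe[np.isfinite(fe)])

    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    p_blocks = np.empty((n_blocks, len(centers)))
    masses = np.empty(n_blocks)
    for k in range(n_blocks):
        sl = slice(bounds[k], bounds[k + 1])
        h, _ = np.histogram(x[sl], bins=edges, weights=w[sl])
        masses[k] = h.sum()
        p_blocks[k] = h / h.sum() if h.sum() > 0 else np.nan
    wt = masses / masses.sum()
    pbar = wt @ p_blocks
    var = n_blocks / (n_blocks - 1) * np.einsum(
        "k,kj->j", wt ** 2, (p_blocks - pbar) ** 2)
    se_p = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_f = se_p / p_full
    se_f = np.where(np.any(p_blocks == 0, axis=0) | (p_full == 0),
                    np.nan, se_f)
    return FESEstimate(centers, fe, se_f)


def plateau_detect(curve: BlockingCurve, rel_tol: float = 0.10):
    """Convergence check: the blocking curve has plateaued.

    Converged iff the relative change of SE across the last 3 reported
    block sizes stays below ``rel_tol``; the plateau SE is the mean of
    those three values.  Returns (converged, plateau_se).
    """
    if len(curve.block_sizes) < 4:
        raise ValueError("need at least 4 block sizes")
    tail = curve.se[-3:]
    rel = np.abs(np.diff(tail)) / tail[:-1]
    converged = bool(np.all(rel < rel_tol))
    return converged, float(tail.mean())
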