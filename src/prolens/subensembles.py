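"""Cis/trans subensemble decomposition and weighted summary statistics.

A weighted conformer ensemble is split by the isomer state of the peptide
bond preceding a chosen proline; each subensemble keeps its frames in
order, with weights renormalized internally, while the raw weight sums give
the isomer populations.  Summaries mirror the standard characterization of
disordered-peptide subensembles: weighted kernel-density estimates of the
radius of gyration, split-half uncertainties from the two halves of the
frame sequence, per-residue secondary-structure populations from (phi, psi)
regions, and Calpha contact maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ca_contact_map, dihedral_from_points

__all__ = [
    "SubensembleSummary",
    "split_by_isomer",
    "weighted_kde",
    "silverman_bandwidth",
    "half_split_uncertainty",
    "ss_classify",
    "ss_populations",
    "summarize_subensembles",
]


@dataclass
class SubensembleSummary:
    isomer: str
    population: float
    population_sd: float
    mean_rg: float
    mean_rg_sd: float
    kde_grid: np.ndarray
    kde_density: np.ndarray
    contact_map: np.ndarray


def split_by_isomer(ensemble, proline_res: int):
    """Split an ensemble into cis and trans subensembles at a proline.

    Returns (cis_ensemble, trans_ensemble, populations) where populations
    maps label -> prior weight sum; the two populations add to 1 exactly.
    Subensemble weights are renormalized to 1; an empty subensemble is
    returned as None with population 0.
    """
    labels = ensemble.isomer_labels(proline_res)
    out = {}
    pops = {}
    for lab in ("cis", "trans"):
        idx = np.flatnonzero(labels == lab)
        pops[lab] = float(ensemble.weights[idx].sum())
        out[lab] = ensemble.subset(idx) if len(idx) else None
    # enforce exact complementarity against round-off
    pops["trans"] = 1.0 - pops["cis"]
    return out["cis"], out["trans"], pops


def silverman_bandwidth(values, weights=None) -> float:
    """Silverman's rule of thumb using the weighted effective sample size
    n_eff = 1 / sum(w^2)."""
    x = np.asarray(values, dtype=float)
    if weights is None:
        w = np.full(len(x), 1.0 / len(x))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mu = w @ x
    sd = np.sqrt(w @ (x - mu) ** 2)
    q75, q25 = _weighted_quantiles(x, w, (0.75, 0.25))
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    n_eff = 1.0 / np.sum(w ** 2)
    scale = max(abs(mu), 1.0)
    if spread <= 1e-12 * scale:      # degenerate input: near-delta kernel
        return 1e-6 * scale
    return float(0.9 * spread * n_eff ** (-0.2))


def _weighted_quantiles(x, w, qs):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return tuple(float(np.interp(q, cw, x[order])) for q in qs)


def weighted_kde(values, weights=None, bandwidth=None, grid=None):
    """Weighted Gaussian kernel density estimate on a grid.

    density(x) = sum_i w_i K_h(x - v_i) with K_h a normal kernel of SD
    ``bandwidth`` (Silverman default on the weighted effective sample
    size).  Returns (grid, density); the density integrates to 1 over a
    grid that covers the data within a few bandwidths.  Zero-variance input
    yields a narrow near-delta peak rather than an error.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    h = silverman_bandwidth(x, w) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        lo, hi = x.min() - 5 * h, x.max() + 5 * h
        grid = np.linspace(lo, hi, 512)
    else:
        grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / h
    dens = (w[None, :] * np.exp(-0.5 * z ** 2)).sum(axis=1) / (
        h * np.sqrt(2 * np.pi))
    return grid, dens


def half_split_uncertainty(metric, ensemble) -> float:
    """Standard deviation between the metric on the first and second halves
    of the frame sequence: |a - b| / sqrt(2) (two-point SD, ddof=1)."""
    n = ensemble.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    half = n // 2
    a = metric(ensemble.subset(np.arange(half)))
    b = metric(ensemble.subset(np.arange(half, n)))
    return float(abs(a - b) / np.sqrt(2.0))


def ss_classify(phi: float, psi: float) -> str:
    """Secondary-structure region from one (phi, psi) pair in degrees.

    helix: phi in (-100, -30) and psi in (-77, -7);
    strand: phi in (-180, -90) and (psi in (90, 180] or psi in (-180, -170));
    otherwise coil.
    """
    if -100.0 < phi < -30.0 and -77.0 < psi < -7.0:
        return "helix"
    if -180.0 < phi < -90.0 and (90.0 < psi <= 180.0 or -180.0 < psi < -170.0):
        return "strand"
    return "coil"


def ss_populations(ensemble):
    """Weight-averaged helix/strand/coil populations per residue.

    Terminal residues lack phi or psi and are excluded; returns a dict
    residue_id -> {helix, strand, coil} with fractions summing to 1.
    """
    top = ensemble.topology
    c = ensemble.coords
    ix = top.atom_index
    w = ensemble.weights
    out = {}
    for rid in range(2, top.n_residues):
        phi = dihedral_from_points(c[:, ix(rid - 1, "C")], c[:, ix(rid, "N")],
                                   c[:, ix(rid, "CA")], c[:, ix(rid, "C")])
        psi = dihedral_from_points(c[:, ix(rid, "N")], c[:, ix(rid, "CA")],
                                   c[:, ix(rid, "C")], c[:, ix(rid + 1, "N")])
        helix = (-100.0 < phi) & (phi < -30.0) & (-77.0 < psi) & (psi < -7.0)
        strand = (-180.0 < phi) & (phi < -90.0) & (
            ((90.0 < psi) & (psi <= 180.0)) | ((-180.0 < psi) & (psi < -170.0)))
        p_h = float(w[helix].sum())
        p_s = float(w[strand & ~helix].sum())
        out[rid] = {"helix": p_h, "strand": p_s, "coil": 1.0 - p_h - p_s}
    return out


def _mean_rg(ens):
    from .geometry import radius_of_gyration
    rg = radius_of_gyration(ens.coords, masses=ens.masses)
    return float(ens.weights @ rg)


def summarize_subensembles(ensemble, proline_res: int, cutoff: float = 0.8,
                           kde_grid=None):
    """Per-isomer populations, Rg statistics, KDE and contact map, with
    split-half uncertainties; returns a dict label -> SubensembleSummary."""
    from .geometry import radius_of_gyration

    cis, trans, pops = split_by_isomer(ensemble, proline_res)
    if kde_grid is None:
        rg_all = radius_of_gyration(ensemble.coords, masses=ensemble.masses)
        h = silverman_bandwidth(rg_all, ensemble.weights)
        kde_grid = np.linspace(rg_all.min() - 5 * h, rg_all.max() + 5 * h, 512)

    def pop_metric(lab):
        return lambda ens: float(
            ens.weights[ens.isomer_labels(proline_res) == lab].sum())

    out = {}
    for lab, sub in (("cis", cis), ("trans", trans)):
        if sub is None:
            out[lab] = SubensembleSummary(lab, pops[lab], 0.0, np.nan, np.nan,
                                          np.asarray(kde_grid),
                                          np.zeros(len(kde_grid)),
                                          np.zeros((0, 0)))
            continue
        rg = radius_of_gyration(sub.coords, masses=sub.masses)
        _, dens = weighted_kde(rg, sub.weights, grid=kde_grid)
        out[lab] = SubensembleSummary(
            isomer=lab,
            population=pops[lab],
            population_sd=half_split_uncertainty(pop_metric(lab), ensemble),
            mean_rg=float(sub.weights @ rg),
            mean_rg_sd=half_split_uncertainty(_mean_rg, sub),
            kde_grid=np.asarray(kde_grid),
            kde_density=dens,
            contact_map=ca_contact_map(sub.ca_coords(), sub.weights, cutoff),
        )
    return out
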