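"""Synthetic conformer ensembles of a disordered peptide.

This module is the desk-scale stand-in for enhanced-sampling trajectories: it
generates backbone ensembles of a proline-containing disordered peptide with
a controllable cis-proline fraction, controllable compactness, and per-frame
statistical weights, plus small tabular fixtures that emulate the NMR
measurements analysed elsewhere in the package (two-state peak volumes
obeying a van 't Hoff law, monoexponential relaxation decays, and
Stejskal-Tanner diffusion decays).

The default configuration emulates the 21-residue C-terminal region of
SARS-CoV-2 ORF6 (sequence SKSLTENKYSQLDEEQPMEID, single proline at position
17; residue 57 in full-length numbering).  Backbone (phi, psi) pairs are
drawn from a three-basin coil-library-like mixture (PPII / beta / alpha-R),
the peptide-bond omega angles are nearly planar, and self-clashing frames
are rejected and redrawn.  An optional acceptance bias on the radius of
gyration produces more compact ensembles without changing the local
dihedral statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .geometry import (
    BackboneGeometry,
    Conformer,
    backbone_topology,
    build_chain_coords,
    classify_isomer,
    cv_series,
    dihedral_from_points,
    radius_of_gyration,
)

__all__ = [
    "ORF6_CTR_SEQUENCE",
    "GAS_CONSTANT",
    "GeneratorConfig",
    "Ensemble",
    "sample_ensemble",
    "attach_weights",
    "synthetic_peak_volumes",
    "synthetic_relaxation_decay",
    "synthetic_dosy_decay",
]

ORF6_CTR_SEQUENCE = "SKSLTENKYSQLDEEQPMEID"

#: molar gas constant, J K^-1 mol^-1
GAS_CONSTANT = 8.314

#: molar gas constant in kJ mol^-1 K^-1 (for bias potentials in kJ/mol)
_R_KJ = 8.314462618e-3


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-ensemble generator.

    ``basin_probs`` are the sampling probabilities of the PPII, beta and
    alpha-R (phi, psi) basins and must sum to 1.  ``cis_fraction`` is the
    probability that the omega angle preceding the proline is drawn around
    0 deg instead of 180 deg.  ``compaction`` is the exponent c of the
    acceptance bias min(1, (rg_ref/Rg)^c); c = 0 disables it.
    """

    sequence: str = ORF6_CTR_SEQUENCE
    proline_position: int = 17
    n_conformers: int = 1000
    cis_fraction: float = 0.10
    basin_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)
    basin_centers: tuple[tuple[float, float], ...] = (
        (-75.0, 150.0),   # PPII
        (-120.0, 130.0),  # beta
        (-60.0, -45.0),   # alpha-R
    )
    basin_sd: float = 15.0
    proline_phi: float = -65.0
    omega_sd: float = 8.0
    compaction: float = 0.0
    rg_ref: float = 0.8
    clash_distance: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.basin_probs) - 1.0) > 1e-12:
            raise ValueError("basin probabilities must sum to 1")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError("cis_fraction must lie in [0, 1]")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        p = self.proline_position
        if not (1 <= p <= len(self.sequence)) or self.sequence[p - 1] != "P":
            raise ValueError(
                f"proline_position {p} does not point at a P in the sequence")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Ensemble:
    """An ordered set of conformers sharing one topology, with prior weights.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm; ``weights`` are
    nonnegative and sum to 1.  ``topology`` is a template conformer providing
    atom names/residues/masses (its own coordinates are frame 0).
    """

    topology: Conformer
    coords: np.ndarray
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] != len(self.weights):
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching weights")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def masses(self) -> np.ndarray:
        return self.topology.masses

    def frame(self, i: int) -> Conformer:
        return self.topology.with_coords(self.coords[i])

    def ca_coords(self) -> np.ndarray:
        sel = self.topology.atom_names == "CA"
        return self.coords[:, sel, :]

    def cv(self, name: str):
        return cv_series(self, name)

    def omega_at(self, res_id: int) -> np.ndarray:
        """Peptide-bond omega angle (deg) preceding residue ``res_id``, per frame."""
        ix = self.topology.atom_index
        c = self.coords
        return np.atleast_1d(dihedral_from_points(
            c[:, ix(res_id - 1, "CA")], c[:, ix(res_id - 1, "C")],
            c[:, ix(res_id, "N")], c[:, ix(res_id, "CA")]))

    def isomer_labels(self, res_id: int) -> np.ndarray:
        return np.atleast_1d(classify_isomer(self.omega_at(res_id)))

    def subset(self, indices, renormalize: bool = True) -> "Ensemble":
        idx = np.asarray(indices)
        w = self.weights[idx]
        total = w.sum()
        if renormalize:
            if total <= 0:
                raise ValueError("cannot renormalize zero-weight subset")
            w = w / total
        return Ensemble(self.topology, self.coords[idx], w,
                        dict(self.metadata, parent_weight=float(total)))

    def with_weights(self, weights: np.ndarray, **meta) -> "Ensemble":
        return Ensemble(self.topology, self.coords,
                        np.asarray(weights, dtype=float),
                        dict(self.metadata, **meta))


def _clash_pairs(sequence: str):
    """Index pairs of atoms separated by >= 3 bonds in the bond graph."""
    names, rids, _, _, _ = backbone_topology(sequence)
    idx = {(int(r), str(n)): i for i, (r, n) in enumerate(zip(rids, names))}
    bonds = []
    for i in range(1, len(sequence) + 1):
        bonds += [(idx[(i, "N")], idx[(i, "CA")]),
                  (idx[(i, "CA")], idx[(i, "C")]),
                  (idx[(i, "C")], idx[(i, "O")])]
        if (i, "CD") in idx:
            bonds.append((idx[(i, "N")], idx[(i, "CD")]))
        if i > 1:
            bonds.append((idx[(i - 1, "C")], idx[(i, "N")]))
    n = len(names)
    rows = [b[0] for b in bonds] + [b[1] for b in bonds]
    cols = [b[1] for b in bonds] + [b[0] for b in bonds]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(graph, method="D", unweighted=True)
    ii, jj = np.triu_indices(n, k=1)
    far = dist[ii, jj] >= 3
    return ii[far], jj[far]


def sample_ensemble(config: GeneratorConfig) -> Ensemble:
    """Draw an ensemble of self-avoiding backbone conformers.

    Each frame draws per-residue (phi, psi) from the basin mixture and
    near-planar omega angles (cis with probability ``cis_fraction`` at the
    proline, trans otherwise); Cartesian coordinates are rebuilt by the
    internal-coordinate chain builder; frames with any nonbonded atom pair
    closer than ``clash_distance`` are rejected and redrawn, and compaction
    biases acceptance by min(1, (rg_ref/Rg)^c).  The same config and seed
    reproduce the ensemble bit for bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_res = len(cfg.sequence)
    pro = cfg.proline_position
    geom = BackboneGeometry()
    ii, jj = _clash_pairs(cfg.sequence)
    names, rids, rnames, elements, masses = backbone_topology(cfg.sequence)

    centers = np.asarray(cfg.basin_centers)
    probs = np.asarray(cfg.basin_probs)

    def draw(n, cis: bool):
        basin = rng.choice(len(probs), size=(n, n_res), p=probs)
        phi = rng.normal(centers[basin, 0], cfg.basin_sd)
        psi = rng.normal(centers[basin, 1], cfg.basin_sd)
        phi[:, pro - 1] = cfg.proline_phi
        omega = rng.normal(180.0, cfg.omega_sd, size=(n, n_res))
        if cis:
            omega[:, pro - 1] = rng.normal(0.0, cfg.omega_sd, size=n)
        return phi, psi, omega

    # The isomer label of every output frame is fixed up front; rejection
    # sampling then redraws within the label stratum, so clash and
    # compaction filters cannot bias the realized cis fraction away from
    # its binomial draw.
    labels_cis = rng.random(cfg.n_conformers) < cfg.cis_fraction
    accepted = np.empty((cfg.n_conformers, len(names), 3))
    n_attempts = 0
    for cis in (False, True):
        slots = np.flatnonzero(labels_cis == cis)
        n_have = 0
        while n_have < len(slots):
            batch = min(max(2 * (len(slots) - n_have), 64), 20000)
            phi, psi, omega = draw(batch, cis)
            coords = build_chain_coords(cfg.sequence, phi, psi, omega, geom)
            d = np.linalg.norm(coords[:, ii, :] - coords[:, jj, :], axis=-1)
            ok = d.min(axis=1) >= cfg.clash_distance
            if cfg.compaction != 0.0:
                rg = radius_of_gyration(coords, masses=masses)
                p_acc = np.minimum(1.0, (cfg.rg_ref / rg) ** cfg.compaction)
                ok &= rng.random(batch) < p_acc
            n_attempts += batch
            sel = coords[ok]
            take = min(len(sel), len(slots) - n_have)
            accepted[slots[n_have:n_have + take]] = sel[:take]
            n_have += take
            if n_attempts >= 100_000 and n_have < 0.01 * n_attempts:
                raise RuntimeError(
                    f"rejection rate above 99% ({n_have}/{n_attempts} accepted); "
                    "loosen clash_distance or compaction")

    topo = Conformer(names, rids, rnames, elements, masses, accepted[0])
    weights = np.full(cfg.n_conformers, 1.0 / cfg.n_conformers)
    meta = {"config": asdict(cfg), "config_hash": cfg.digest(),
            "seed": cfg.seed, "n_attempts": n_attempts}
    return Ensemble(topo, accepted, weights, meta)


def attach_weights(ensemble: Ensemble, mode: str = "uniform",
                   bias_kj_mol=None, temperature: float = 310.0) -> Ensemble:
    """Attach per-frame statistical weights.

    ``uniform`` sets w_i = 1/n.  ``from_bias`` applies the final-bias
    estimator w_i proportional to exp(V_i / kB T) for bias potentials V_i in
    kJ/mol at the given temperature, normalized over frames.
    """
    n = ensemble.n_frames
    if mode == "uniform":
        w = np.full(n, 1.0 / n)
        return ensemble.with_weights(w, weight_mode="uniform")
    if mode == "from_bias":
        v = np.asarray(bias_kj_mol, dtype=float)
        if v.shape != (n,):
            raise ValueError(f"bias must have one value per frame ({n})")
        if not np.all(np.isfinite(v)):
            raise ValueError("bias values must be finite")
        x = v / (_R_KJ * temperature)
        x -= x.max()
        w = np.exp(x)
        w /= w.sum()
        return ensemble.with_weights(w, weight_mode="from_bias",
                                     temperature=temperature)
    raise ValueError(f"unknown weight mode {mode!r}")


# ---------------------------------------------------------------------------
# NMR tabular fixtures


def synthetic_peak_volumes(delta_h: float, delta_s: float, temperatures,
                           noise_sd: float = 0.0, seed: int = 0,
                           residues=("E55", "Q56", "E59"),
                           v_trans: float = 100.0) -> pd.DataFrame:
    """Two-state peak-volume table obeying a van 't Hoff law.

    For each residue and temperature T the cis/trans volume ratio is
    K(T) = exp(-(delta_h - T*delta_s) / (R*T)) with delta_h in J/mol and
    delta_s in J/(K*mol); multiplicative log-normal noise of standard
    deviation ``noise_sd`` (on ln V) is applied per peak when nonzero.
    """
    temps = np.asarray(temperatures, dtype=float)
    if np.any(temps < 270.0) or np.any(temps > 320.0):
        raise ValueError("temperatures must lie within 270-320 K")
    rng = np.random.default_rng(seed)
    rows = []
    for res in residues:
        for t in temps:
            k = np.exp(-(delta_h - t * delta_s) / (GAS_CONSTANT * t))
            vt, vc = v_trans, v_trans * k
            if noise_sd > 0:
                vt *= np.exp(rng.normal(0.0, noise_sd))
                vc *= np.exp(rng.normal(0.0, noise_sd))
            rows.append((res, "trans", t, vt))
            rows.append((res, "cis", t, vc))
    return pd.DataFrame(rows, columns=["residue", "isomer",
                                       "temperature_K", "volume"])


def synthetic_relaxation_decay(rate: float, delays, i0: float = 100.0,
                               noise_sd: float = 0.0,
                               seed: int = 0) -> pd.DataFrame:
    """Monoexponential intensity decay I(t) = I0 exp(-R t) with optional
    additive Gaussian noise of ``noise_sd`` (fraction of I0)."""
    t = np.asarray(delays, dtype=float)
    intens = i0 * np.exp(-rate * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, noise_sd * i0, size=t.shape)
    return pd.DataFrame({"delay_s": t, "intensity": intens})


def synthetic_dosy_decay(diffusion: float, gradients, delta: float,
                         big_delta: float, gamma: float = 2.6752218744e8,
                         i0: float = 100.0, noise_sd: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Stejskal-Tanner diffusion decay.

    I(g) = I0 exp(-D gamma^2 g^2 delta^2 (Delta - delta/3)) with gradient
    strengths in T/m, pulse length ``delta`` and diffusion delay
    ``big_delta`` in s, and D in m^2/s.
    """
    g = np.asarray(gradients, dtype=float)
    if big_delta <= delta / 3.0:
        raise ValueError("diffusion delay must exceed delta/3")
    b = (gamma * g * delta) ** 2 * (big_delta - delta / 3.0)
    intens = i0 * np.exp(-diffusion * b)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens * np.exp(rng.normal(0.0, noise_sd, size=g.shape))
    return pd.DataFrame({"gradient_T_per_m": g, "intensity": intens})
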