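"""Backbone geometry primitives for peptide conformer ensembles.

Conformers are stored as flat atom arrays (names, residue indices, coordinates
in nanometres).  The module provides an internal-coordinate chain builder
(NeRF-style sequential atom placement), signed torsion angles, the cis/trans
classifier for the peptide-bond omega angle, the improper zeta angle used to
monitor proline isomerization, and the per-frame collective variables used
throughout the package: radius of gyration, end-to-end distance, consecutive
psi-dihedral correlation, and Calpha contact maps.

All angles cross the API in degrees, signed, in (-180, 180]; torsions follow
the IUPAC convention (0 deg = cis/syn, +-180 deg = trans/anti).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ATOM_MASSES",
    "AMINO3",
    "BackboneGeometry",
    "DihedralSpec",
    "Conformer",
    "CVSeries",
    "dihedral",
    "dihedral_from_points",
    "classify_isomer",
    "build_backbone",
    "build_chain_coords",
    "backbone_topology",
    "radius_of_gyration",
    "end_to_end",
    "dihedral_correlation",
    "ca_contact_map",
    "cv_series",
]

# Average atomic masses in Da.
ATOM_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

AMINO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal bond lengths (nm) and angles (degrees) for chain construction.

    Defaults are canonical peptide values (Engh-Huber-like); every parameter
    is overridable.  ``r_n_cd`` and ``ang_c_n_cd`` control placement of the
    proline ring delta carbon, which is kept in the amide plane.
    """

    r_n_ca: float = 0.1458
    r_ca_c: float = 0.1525
    r_c_n: float = 0.1329
    r_c_o: float = 0.1231
    r_n_cd: float = 0.1468
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_c_n_cd: float = 125.0

    def __post_init__(self):
        for name in ("r_n_ca", "r_ca_c", "r_c_n", "r_c_o", "r_n_cd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name} must be positive")
        for name in ("ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca",
                     "ang_ca_c_o", "ang_c_n_cd"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"bond angle {name} must lie in (0, 180) deg")


@dataclass(frozen=True)
class DihedralSpec:
    """A named torsion defined by four atom indices in torsion order."""

    name: str
    indices: tuple[int, int, int, int]

    def __post_init__(self):
        if len(set(self.indices)) != 4:
            raise ValueError("dihedral requires four distinct atom indices")


@dataclass
class Conformer:
    """A single-chain conformer: parallel atom arrays plus coordinates in nm.

    ``res_ids`` are 1-based along the chain.  Atom order is stable so that
    conformers of one ensemble share indexing.
    """

    atom_names: np.ndarray          # (n_atoms,) str
    res_ids: np.ndarray             # (n_atoms,) int, 1-based
    res_names: np.ndarray           # (n_atoms,) 3-letter str
    elements: np.ndarray            # (n_atoms,) str
    masses: np.ndarray              # (n_atoms,) float, Da
    coords: np.ndarray              # (n_atoms, 3) float, nm
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("conformer coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("atom masses must be positive")
        if not self._index:
            self._index = {
                (int(r), str(n)): i
                for i, (r, n) in enumerate(zip(self.res_ids, self.atom_names))
            }

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return int(self.res_ids.max())

    def atom_index(self, res_id: int, name: str) -> int:
        try:
            return self._index[(int(res_id), name)]
        except KeyError:
            raise KeyError(f"no atom {name!r} in residue {res_id}") from None

    def position(self, res_id: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(res_id, name)]

    def with_coords(self, coords: np.ndarray) -> "Conformer":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def sequence(self) -> str:
        rev3 = {v: k for k, v in AMINO3.items()}
        out = []
        for rid in range(1, self.n_residues + 1):
            name3 = self.res_names[self.res_ids == rid][0]
            out.append(rev3.get(str(name3), "X"))
        return "".join(out)


@dataclass
class CVSeries:
    """One collective-variable value per ensemble frame."""

    name: str
    values: np.ndarray
    units: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"CV series {self.name!r} contains non-finite values")


# ---------------------------------------------------------------------------
# torsions


def dihedral_from_points(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle(s) in degrees, range (-180, 180].

    Accepts arrays with an arbitrary number of leading dimensions; the last
    axis holds xyz.  0 deg is the syn/cis (eclipsed) arrangement.  Raises if
    three consecutive points are collinear (torsion undefined).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1, axis=-1)
    n2n = np.linalg.norm(n2, axis=-1)
    scale = np.linalg.norm(b1, axis=-1) * np.maximum(
        np.linalg.norm(b0, axis=-1), np.linalg.norm(b2, axis=-1)
    )
    if np.any(n1n <= 1e-12 * scale) or np.any(n2n <= 1e-12 * scale):
        raise ValueError("undefined torsion: collinear bond vectors")
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    ang = -np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    ang = np.where(ang <= -180.0 + 1e-12, ang + 360.0, ang)
    return ang if ang.ndim else float(ang)


def dihedral(conformer: Conformer, spec: DihedralSpec) -> float:
    """Torsion angle (degrees) of the four atoms named by ``spec``."""
    i, j, k, l = spec.indices
    n = conformer.n_atoms
    for idx in spec.indices:
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for {n} atoms")
    c = conformer.coords
    return float(dihedral_from_points(c[i], c[j], c[k], c[l]))


def classify_isomer(omega_degrees: float | np.ndarray):
    """Classify a peptide-bond omega angle as ``cis`` or ``trans``.

    cis iff |omega| < 90 deg after wrapping into (-180, 180]; the boundary
    value 90 deg is assigned trans.
    """
    w = np.asarray(omega_degrees, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("omega must be finite")
    wrapped = np.abs((w + 180.0) % 360.0 - 180.0)
    lab = np.where(wrapped < 90.0, "cis", "trans")
    return str(lab) if lab.ndim == 0 else lab


# ---------------------------------------------------------------------------
# chain construction


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d from positions a, b, c (vectorized).

    d is at distance ``bond`` from c, with angle b-c-d = ``angle_deg`` and
    torsion a-b-c-d = ``torsion_deg`` (IUPAC sign convention).
    """
    theta = np.radians(angle_deg)
    chi = np.radians(np.asarray(torsion_deg, dtype=float))
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    # local displacement: x along bc, y along m, z along n
    d2 = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(chi),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    return c + (
        d2[..., 0:1] * bc + d2[..., 1:2] * m + d2[..., 2:3] * n
    )


def backbone_topology(sequence: str):
    """Atom names / residue ids / residue names / elements / masses for a
    backbone-only chain (N, CA, C, O per residue; CD appended for proline)."""
    names, rids, rnames, elements = [], [], [], []
    for i, aa in enumerate(sequence, start=1):
        if aa not in AMINO3:
            raise ValueError(f"unknown residue code {aa!r} at position {i}")
        res3 = AMINO3[aa]
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            names.append(nm)
            rids.append(i)
            rnames.append(res3)
            elements.append(el)
        if aa == "P":
            names.append("CD")
            rids.append(i)
            rnames.append(res3)
            elements.append("C")
    masses = np.array([ATOM_MASSES[e] for e in elements])
    return (
        np.array(names),
        np.array(rids, dtype=int),
        np.array(rnames),
        np.array(elements),
        masses,
    )


def build_chain_coords(sequence: str, phi, psi, omega,
                       geometry: BackboneGeometry | None = None) -> np.ndarray:
    """Build Cartesian coordinates for one or many frames at once.

    ``phi``, ``psi``, ``omega`` have shape (n_res,) or (n_frames, n_res) in
    degrees.  phi[...,0] and omega[...,0] are ignored (undefined at the N
    terminus); psi of the last residue orients its carbonyl oxygen.  Returns
    coordinates of shape (n_frames, n_atoms, 3) in nm; 1-D dihedral input is
    treated as a single frame (n_frames = 1).
    """
    geom = geometry or BackboneGeometry()
    n_res = len(sequence)
    if n_res < 2:
        raise ValueError("sequence must contain at least 2 residues")
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    for arr, nm in ((phi, "phi"), (psi, "psi"), (omega, "omega")):
        if arr.shape[-1] != n_res:
            raise ValueError(
                f"{nm} must provide one angle per residue "
                f"(got {arr.shape[-1]}, need {n_res})"
            )
        if not np.all(np.isfinite(arr)):
            bad = int(np.argwhere(~np.isfinite(arr))[0][-1]) + 1
            raise ValueError(f"missing/non-finite {nm} for residue {bad}")
    nf = max(phi.shape[0], psi.shape[0], omega.shape[0])
    phi = np.broadcast_to(phi, (nf, n_res))
    psi = np.broadcast_to(psi, (nf, n_res))
    omega = np.broadcast_to(omega, (nf, n_res))

    names, rids, _, _, _ = backbone_topology(sequence)
    n_atoms = len(names)
    coords = np.empty((nf, n_atoms, 3))
    idx = {(int(r), str(n)): i for i, (r, n) in enumerate(zip(rids, names))}

    ang_nca_c = geom.ang_n_ca_c
    # first residue: N at origin, CA on +x, C in the xy-plane
    N1 = np.zeros((nf, 3))
    CA1 = np.zeros((nf, 3))
    CA1[:, 0] = geom.r_n_ca
    th = np.radians(ang_nca_c)
    C1 = CA1 + geom.r_ca_c * np.stack(
        [np.full(nf, -np.cos(th)), np.full(nf, np.sin(th)), np.zeros(nf)], axis=-1
    )
    coords[:, idx[(1, "N")]] = N1
    coords[:, idx[(1, "CA")]] = CA1
    coords[:, idx[(1, "C")]] = C1

    prevN, prevCA, prevC = N1, CA1, C1
    for i in range(2, n_res + 1):
        # N_i: torsion psi_{i-1} about CA_{i-1}-C_{i-1}
        Ni = _place_atom(prevN, prevCA, prevC, geom.r_c_n,
                         geom.ang_ca_c_n, psi[:, i - 2])
        # CA_i: torsion omega_i about C_{i-1}-N_i
        CAi = _place_atom(prevCA, prevC, Ni, geom.r_n_ca,
                          geom.ang_c_n_ca, omega[:, i - 1])
        # C_i: torsion phi_i about N_i-CA_i
        Ci = _place_atom(prevC, Ni, CAi, geom.r_ca_c,
                         geom.ang_n_ca_c, phi[:, i - 1])
        # carbonyl O of residue i-1: anti to N_i across the CA-C bond
        Oi_1 = _place_atom(Ni, prevCA, prevC, geom.r_c_o,
                           geom.ang_ca_c_o, np.full(nf, 180.0))
        coords[:, idx[(i - 1, "O")]] = Oi_1
        if sequence[i - 1] == "P":
            # proline CD: in the amide plane, anti to CA_i across C-N
            CDi = _place_atom(prevCA, prevC, Ni, geom.r_n_cd,
                              geom.ang_c_n_cd, omega[:, i - 1] + 180.0)
            coords[:, idx[(i, "CD")]] = CDi
        coords[:, idx[(i, "N")]] = Ni
        coords[:, idx[(i, "CA")]] = CAi
        coords[:, idx[(i, "C")]] = Ci
        prevN, prevCA, prevC = Ni, CAi, Ci
    # O of the final residue from its own psi (anti to the psi direction)
    On = _place_atom(prevN, prevCA, prevC, geom.r_c_o, geom.ang_ca_c_o,
                     psi[:, n_res - 1] + 180.0)
    coords[:, idx[(n_res, "O")]] = On
    if sequence[0] == "P":
        # N-terminal proline: CD placed from the first-residue frame
        CD1 = _place_atom(coords[:, idx[(1, "C")]], coords[:, idx[(1, "CA")]],
                          coords[:, idx[(1, "N")]], geom.r_n_cd,
                          geom.ang_c_n_cd, np.full(nf, 180.0))
        coords[:, idx[(1, "CD")]] = CD1
    return coords


def build_backbone(sequence: str, phi, psi, omega,
                   geometry: BackboneGeometry | None = None) -> Conformer:
    """Build a single backbone conformer from per-residue dihedrals.

    See :func:`build_chain_coords` for the dihedral conventions.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 1:
        raise ValueError("build_backbone expects 1-D dihedral arrays")
    coords = build_chain_coords(sequence, phi, psi, omega, geometry)[0]
    names, rids, rnames, elements, masses = backbone_topology(sequence)
    return Conformer(names, rids, rnames, elements, masses, coords)


# ---------------------------------------------------------------------------
# scalar observables


def radius_of_gyration(conformer_or_coords, masses=None,
                       mass_weighted: bool = True):
    """Radius of gyration in nm: sqrt(sum m |r - r_com|^2 / sum m).

    Accepts a :class:`Conformer` or a coordinate array with shape
    (..., n_atoms, 3); for arrays, ``masses`` applies when mass-weighting.
    """
    if isinstance(conformer_or_coords, Conformer):
        coords = conformer_or_coords.coords
        masses = conformer_or_coords.masses
    else:
        coords = np.asarray(conformer_or_coords, dtype=float)
    if coords.shape[-2] < 1:
        raise ValueError("need at least one atom")
    if mass_weighted and masses is not None:
        m = np.asarray(masses, dtype=float)
    else:
        m = np.ones(coords.shape[-2])
    m = m / m.sum()
    com = np.einsum("a,...ax->...x", m, coords)
    d2 = np.sum((coords - com[..., None, :]) ** 2, axis=-1)
    rg = np.sqrt(np.einsum("a,...a->...", m, d2))
    return float(rg) if rg.ndim == 0 else rg


def end_to_end(conformer: Conformer) -> float:
    """Distance (nm) between the Calpha atoms of the first and last residues."""
    if conformer.n_residues < 2:
        raise ValueError("need at least 2 residues")
    a = conformer.position(1, "CA")
    b = conformer.position(conformer.n_residues, "CA")
    return float(np.linalg.norm(b - a))


def _psi_angles(conformer: Conformer) -> np.ndarray:
    """psi_i = torsion(N_i, CA_i, C_i, N_{i+1}) for i = 1..n-1, degrees."""
    n = conformer.n_residues
    c = conformer.coords
    ix = conformer.atom_index
    p0 = np.stack([c[ix(i, "N")] for i in range(1, n)])
    p1 = np.stack([c[ix(i, "CA")] for i in range(1, n)])
    p2 = np.stack([c[ix(i, "C")] for i in range(1, n)])
    p3 = np.stack([c[ix(i + 1, "N")] for i in range(1, n)])
    return np.atleast_1d(dihedral_from_points(p0, p1, p2, p3))


def dihedral_correlation(conformer: Conformer) -> float:
    """Sum over consecutive psi pairs of (1 + cos(psi_i - psi_{i+1})) / 2.

    Lies in [0, n_pairs]; large values indicate correlated backbone psi
    angles along the chain.
    """
    if conformer.n_residues < 3:
        raise ValueError("need at least 3 residues")
    psi = np.radians(_psi_angles(conformer))
    return float(np.sum(0.5 * (1.0 + np.cos(np.diff(psi)))))


def ca_contact_map(ca_coords: np.ndarray, weights: np.ndarray,
                   cutoff: float = 0.8) -> np.ndarray:
    """Weighted Calpha contact-probability matrix.

    ``ca_coords`` has shape (n_frames, n_res, 3) in nm; entry (i, j) is the
    weighted fraction of frames with |CA_i - CA_j| < cutoff.  The diagonal is
    1 by construction and the matrix is exactly symmetric.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = np.asarray(ca_coords, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("weights must be normalized")
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    contact = (dist < cutoff).astype(float)
    cmap = np.einsum("f,fij->ij", w, contact)
    cmap = 0.5 * (cmap + cmap.T)
    np.fill_diagonal(cmap, 1.0)
    return cmap


def cv_series(ensemble, name: str) -> CVSeries:
    """Extract a per-frame collective-variable series from an ensemble.

    Supported names: ``rg``, ``end_to_end``, ``dihcor``, ``psi:<res>``,
    ``zeta:<res>`` (zeta requires a proline at <res>).  The ensemble object
    must expose ``coords`` (n_frames, n_atoms, 3), ``masses`` and a
    ``topology`` conformer for atom lookup.
    """
    top = ensemble.topology
    coords = ensemble.coords
    ix = top.atom_index
    if name == "rg":
        vals = radius_of_gyration(coords, masses=top.masses)
        return CVSeries("rg", vals, "nm")
    if name == "end_to_end":
        a = coords[:, ix(1, "CA")]
        b = coords[:, ix(top.n_residues, "CA")]
        return CVSeries("end_to_end", np.linalg.norm(b - a, axis=-1), "nm")
    if name == "dihcor":
        n = top.n_residues
        psis = []
        for i in range(1, n):
            psis.append(
                dihedral_from_points(coords[:, ix(i, "N")], coords[:, ix(i, "CA")],
                                     coords[:, ix(i, "C")], coords[:, ix(i + 1, "N")])
            )
        psi = np.radians(np.stack(psis, axis=-1))
        vals = np.sum(0.5 * (1.0 + np.cos(np.diff(psi, axis=-1))), axis=-1)
        return CVSeries("dihcor", vals, "dimensionless")
    if ":" in name:
        kind, res_s = name.split(":", 1)
        rid = int(res_s)
        if kind == "psi":
            if rid >= top.n_residues:
                raise ValueError("psi undefined for the last residue")
            vals = dihedral_from_points(
                coords[:, ix(rid, "N")], coords[:, ix(rid, "CA")],
                coords[:, ix(rid, "C")], coords[:, ix(rid + 1, "N")])
            return CVSeries(name, vals, "degrees")
        if kind == "zeta":
            res3 = top.res_names[top.res_ids == rid]
            if len(res3) == 0 or res3[0] != "PRO":
                raise ValueError(f"zeta requires a proline at residue {rid}")
            vals = dihedral_from_points(
                coords[:, ix(rid - 1, "CA")], coords[:, ix(rid - 1, "O")],
                coords[:, ix(rid, "CD")], coords[:, ix(rid, "CA")])
            return CVSeries(name, vals, "degrees")
        if kind == "omega":
            vals = dihedral_from_points(
                coords[:, ix(rid - 1, "CA")], coords[:, ix(rid - 1, "C")],
                coords[:, ix(rid, "N")], coords[:, ix(rid, "CA")])
            return CVSeries(name, vals, "degrees")
    raise ValueError(f"unknown CV name {name!r}")
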