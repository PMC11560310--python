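"""File formats: multi-model PDB ensembles, weight files, SAXS profiles.

Conventions: PDB files are in Angstrom (converted to nm in memory);
weight files are plain text, one weight per line, '#' comments allowed;
SAXS profiles are 3-column text (q, I, sigma) with q in nm^-1 unless the
Angstrom flag is passed.  All tabular results are CSV with header rows.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .ensembles import Ensemble
from .geometry import ATOM_MASSES, Conformer
from .scattering import SAXSProfile

__all__ = [
    "write_ensemble",
    "read_ensemble",
    "write_weights",
    "read_weights",
    "read_saxs",
    "write_saxs",
]


def write_ensemble(ensemble: Ensemble, pdb_path, weights_path=None) -> None:
    """Write a multi-model PDB (one MODEL per frame) and optional weights."""
    top = ensemble.topology
    n_frames, n_atoms = ensemble.coords.shape[:2]
    atoms = struc.AtomArray(n_atoms)
    atoms.chain_id = np.full(n_atoms, "A")
    atoms.res_id = top.res_ids
    atoms.res_name = top.res_names
    atoms.atom_name = top.atom_names
    atoms.element = top.elements
    atoms.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.from_template(atoms, ensemble.coords * 10.0)  # nm -> A
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(pdb_path))
    if weights_path is not None:
        write_weights(ensemble.weights, weights_path,
                      header=_weights_header(ensemble))


def _weights_header(ensemble: Ensemble) -> str:
    meta = ensemble.metadata
    bits = []
    if "seed" in meta:
        bits.append(f"seed={meta['seed']}")
    if "config_hash" in meta:
        bits.append(f"config_hash={meta['config_hash']}")
    return " ".join(bits) if bits else "prior weights"


def read_ensemble(pdb_path, weights_path=None) -> Ensemble:
    """Read a multi-model PDB into an Ensemble (coordinates in nm).

    All models must share the atom layout; weights default to uniform when
    no weight file is given and must match the model count otherwise.
    """
    pdb = PDBFile.read(str(pdb_path))
    try:
        stack = pdb.get_structure()          # AtomArrayStack
    except Exception as exc:
        raise ValueError(
            f"inconsistent atom records across models in {pdb_path}: {exc}"
        ) from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    coords = stack.coord / 10.0              # A -> nm
    elements = np.array([e.capitalize() for e in stack.element])
    masses = np.array([ATOM_MASSES.get(e, 12.011) for e in elements])
    topo = Conformer(
        atom_names=np.array(stack.atom_name),
        res_ids=np.array(stack.res_id, dtype=int),
        res_names=np.array(stack.res_name),
        elements=elements,
        masses=masses,
        coords=coords[0],
    )
    n = coords.shape[0]
    if weights_path is not None:
        w = read_weights(weights_path)
        if len(w) != n:
            raise ValueError(
                f"weight file has {len(w)} entries for {n} models")
    else:
        w = np.full(n, 1.0 / n)
    return Ensemble(topo, coords, w, {"source": str(pdb_path)})


def write_weights(weights, path, header: str = "") -> None:
    w = np.asarray(weights, dtype=float)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for v in w:
            fh.write(f"{v:.12e}\n")


def read_weights(path) -> np.ndarray:
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals.append(float(line))
    w = np.asarray(vals, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return w / total


def read_saxs(path, angstrom: bool = False) -> SAXSProfile:
    """Read a 3-column SAXS text file (q, I[, sigma]); '#' lines skipped.

    ``angstrom=True`` converts q from A^-1 to nm^-1 (factor 10).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"SAXS line needs >= 2 columns: {line!r}")
            rows.append([float(p) for p in parts[:3]])
    if not rows:
        raise ValueError("empty SAXS file")
    ncol = min(len(r) for r in rows)
    arr = np.asarray([r[:ncol] for r in rows], dtype=float)
    q = arr[:, 0] * (10.0 if angstrom else 1.0)
    sigma = arr[:, 2] if ncol >= 3 else None
    return SAXSProfile(q, arr[:, 1], sigma)


def write_saxs(profile: SAXSProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# q_nm^-1 I sigma\n")
        for i in range(len(profile)):
            sig = profile.sigma[i] if profile.sigma is not None else np.nan
            fh.write(f"{profile.q[i]:.6e} {profile.intensity[i]:.6e} {sig:.6e}\n")
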