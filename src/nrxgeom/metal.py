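"""Metal coordination shells and geometry classification.

Protein Ca²⁺ sites are usually 6–7 coordinate, with oxygen donors from
side chains, backbone carbonyls and ordered waters.  This module
collects the inner-sphere ligands of a selected ion and decides
whether their directions best match an ideal octahedron (6 vertices)
or a pentagonal bipyramid (7 vertices) — the two shapes contrasted for
LNS-domain Ca²⁺ sites — by brute-force vertex assignment plus optimal
rotation of the ideal template onto the observed directions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import NrxGeomError
from .model import StructureModel

__all__ = [
    "Ligand",
    "MetalSiteReport",
    "find_ligands",
    "classify_geometry",
    "octahedron_vertices",
    "pentagonal_bipyramid_vertices",
    "analyze_metal_site",
]


def octahedron_vertices() -> np.ndarray:
    """Unit vectors to the 6 vertices of a regular octahedron."""
    return np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )


def pentagonal_bipyramid_vertices() -> np.ndarray:
    """Unit vectors: 5 equatorial (72° apart) + 2 axial."""
    eq = [
        [math.cos(2 * math.pi * k / 5), math.sin(2 * math.pi * k / 5), 0.0]
        for k in range(5)
    ]
    return np.array(eq + [[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]], dtype=float)


@dataclass(frozen=True)
class Ligand:
    chain: str
    auth_number: int
    residue_name: str
    atom_name: str
    role: str  # side_chain_O | main_chain_O | water_O | other
    distance: float


@dataclass
class MetalSiteReport:
    ion: tuple[str, int, str]  # chain, auth_number, residue name
    ligands: list[Ligand]
    n_protein_ligands: int
    n_water_ligands: int
    geometry_class: str
    angular_rmsd: float | None  # degrees; None when class is "other"


def _ligand_role(category: str, atom_name: str, element: str) -> str:
    element = element.upper()
    if category == "water":
        return "water_O"
    if category == "amino_acid" and element == "O":
        # the backbone carbonyl oxygen is named exactly "O" (OXT is terminal
        # carboxylate, counted as side-chain-like here)
        return "main_chain_O" if atom_name == "O" else "side_chain_O"
    return "other"


def find_ligands(
    model: StructureModel,
    ion: tuple[str, int],
    cutoff: float = 3.0,
) -> list[Ligand]:
    """O/N atoms within ``cutoff`` Å of the ion, sorted by distance.

    ``ion`` is (chain, auth_number) of a residue whose category is
    ``ion``.  Roles: backbone carbonyl O → main_chain_O; other protein
    O → side_chain_O; water O → water_O; everything else (e.g. protein
    N) → other.
    """
    chain, number = ion
    ion_res = model.find_residue(chain, number)
    if ion_res.category != "ion":
        raise NrxGeomError(f"residue {chain}/{number} ({ion_res.name}) is not an ion")
    center = ion_res.atoms[0].coord
    out = []
    for cid, res, atom in model.atoms():
        if res is ion_res:
            continue
        if atom.element.upper() not in ("O", "N"):
            continue
        d = float(np.linalg.norm(atom.coord - center))
        if d <= cutoff:
            out.append(
                Ligand(
                    chain=cid,
                    auth_number=res.auth_number,
                    residue_name=res.name,
                    atom_name=atom.name,
                    role=_ligand_role(res.category, atom.name, atom.element),
                    distance=d,
                )
            )
    return sorted(out, key=lambda l: l.distance)


def _best_fit_rmsd(observed: np.ndarray, template: np.ndarray) -> float:
    """Minimal RMS angular deviation (degrees) over all vertex assignments
    and proper rotations of the template onto the observed directions."""
    n = len(observed)
    best = math.inf
    for perm in itertools.permutations(range(n)):
        T = template[list(perm)]
        # Kabsch on unit vectors (both sets centred at the origin)
        H = T.T @ observed
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        rotated = T @ R.T
        cosang = np.clip(np.sum(rotated * observed, axis=1), -1.0, 1.0)
        rms = math.degrees(math.sqrt(np.mean(np.arccos(cosang) ** 2)))
        if rms < best:
            best = rms
            if best == 0.0:
                break
    return best


def classify_geometry(ligand_directions: np.ndarray) -> tuple[str, float | None]:
    """Classify 4–8 unit vectors as octahedral / pentagonal_bipyramid / other.

    n=6 is scored against the regular octahedron, n=7 against the
    pentagonal bipyramid; other counts return ("other", None).  The
    score is the RMS angular deviation after brute-force assignment and
    optimal rotation — invariant under global rotation and ligand
    permutation by construction.
    """
    dirs = np.asarray(ligand_directions, dtype=float)
    if dirs.ndim != 2 or dirs.shape[1] != 3:
        raise NrxGeomError("ligand directions must be (n, 3)")
    n = len(dirs)
    if not 4 <= n <= 8:
        raise NrxGeomError(f"need 4-8 ligand directions, got {n}")
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms < 1e-9):
        raise NrxGeomError("zero-length ligand direction")
    dirs = dirs / norms[:, None]
    if n == 6:
        return "octahedral", _best_fit_rmsd(dirs, octahedron_vertices())
    if n == 7:
        return "pentagonal_bipyramid", _best_fit_rmsd(dirs, pentagonal_bipyramid_vertices())
    return "other", None


def analyze_metal_site(
    model: StructureModel,
    ion: tuple[str, int],
    cutoff: float = 3.0,
) -> MetalSiteReport:
    """Full inner-sphere report: ligands, roles, counts and geometry class."""
    chain, number = ion
    ion_res = model.find_residue(chain, number)
    ligands = find_ligands(model, ion, cutoff)
    center = ion_res.atoms[0].coord
    n_protein = sum(1 for l in ligands if l.role in ("side_chain_O", "main_chain_O"))
    n_water = sum(1 for l in ligands if l.role == "water_O")
    if 4 <= len(ligands) <= 8:
        coords = []
        for l in ligands:
            res = model.find_residue(l.chain, l.auth_number)
            coords.append(res.atom(l.atom_name).coord - center)
        geometry_class, angular_rmsd = classify_geometry(np.vstack(coords))
    else:
        geometry_class, angular_rmsd = "other", None
    return MetalSiteReport(
        ion=(chain, number, ion_res.name),
        ligands=ligands,
        n_protein_ligands=n_protein,
        n_water_ligands=n_water,
        geometry_class=geometry_class,
        angular_rmsd=angular_rmsd,
    )
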