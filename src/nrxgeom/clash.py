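"""Van der Waals clash detection and pivot-rotation clash relief.

A clash is a heavy-atom pair from two sets whose centre distance falls
below r_i + r_j − tolerance.  The hinge scan rotates a mobile segment
rigidly about an axis through a pivot atom and searches a
deterministic (Fibonacci-sphere axes × 1°-grid angles) space for the
smallest rotation that leaves zero clashes against a static partner —
the move a multidomain protein would make to swing one arm clear of a
binding partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, MissingRadiusError, NrxGeomError
from .model import StructureModel
from .sasa import DEFAULT_RADII, sphere_points

__all__ = [
    "ClashParams",
    "AtomSet",
    "Clash",
    "HingeScanResult",
    "atom_set",
    "detect_clashes",
    "rotate_about_axis",
    "min_relief_rotation",
]


@dataclass(frozen=True)
class ClashParams:
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    overlap_tolerance: float = 0.4
    neighbor_exclusion: int = 2

    def __post_init__(self) -> None:
        if self.overlap_tolerance < 0:
            raise NrxGeomError("overlap tolerance must be >= 0")

    def radius_of(self, element: str, atom_name: str = "") -> float:
        key = element.strip().upper()
        if key not in self.radii_table:
            raise MissingRadiusError(
                f"no van der Waals radius for atom {atom_name or '?'} (element {element!r})"
            )
        return self.radii_table[key]


@dataclass
class AtomSet:
    """Flat view of heavy atoms: coordinates + radii + residue identity."""

    coords: np.ndarray  # (N, 3)
    radii: np.ndarray  # (N,)
    labels: list[tuple[str, int, str]]  # (chain, auth_number, atom name)

    def __len__(self) -> int:
        return len(self.coords)


def atom_set(
    model: StructureModel,
    params: ClashParams | None = None,
    categories: tuple[str, ...] = ("amino_acid",),
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
) -> AtomSet:
    """Collect heavy atoms of the requested categories into an AtomSet."""
    params = params or ClashParams()
    coords, radii, labels = [], [], []
    for cid, res, atom in model.atoms():
        if chain is not None and cid != chain:
            continue
        if res.category not in categories:
            continue
        if residue_range and not (residue_range[0] <= res.auth_number <= residue_range[1]):
            continue
        if atom.element.upper() == "H":
            continue
        coords.append(atom.coord)
        radii.append(params.radius_of(atom.element, atom.name))
        labels.append((cid, res.auth_number, atom.name))
    if not coords:
        raise NrxGeomError("atom set is empty")
    return AtomSet(np.vstack(coords), np.asarray(radii), labels)


@dataclass(frozen=True)
class Clash:
    atom_a: tuple[str, int, str]
    atom_b: tuple[str, int, str]
    distance: float
    overlap: float  # (r_i + r_j − tol) − d, > 0


def _clash_pairs(a: AtomSet, b: AtomSet, tol: float, neighbor_exclusion: int):
    """Index pairs (i, j) violating the contact criterion; KD-tree pruned,
    identical to the all-pairs result."""
    tree_b = cKDTree(b.coords)
    max_cut = float(a.radii.max() + b.radii.max() - tol)
    if max_cut <= 0:
        return []
    hits = []
    candidates = tree_b.query_ball_point(a.coords, max_cut)
    for i, js in enumerate(candidates):
        if not js:
            continue
        js = np.asarray(js)
        d = np.linalg.norm(b.coords[js] - a.coords[i], axis=1)
        cut = a.radii[i] + b.radii[js] - tol
        for j, dist, c in zip(js, d, cut):
            if dist < c:
                ca, na, _ = a.labels[i]
                cb, nb, _ = b.labels[int(j)]
                if ca == cb and abs(na - nb) <= neighbor_exclusion:
                    continue  # covalent neighbourhood, not a clash
                hits.append((i, int(j), float(dist), float(c - dist)))
    return hits


def detect_clashes(setA: AtomSet, setB: AtomSet, params: ClashParams | None = None) -> list[Clash]:
    """All atom pairs of A×B with distance < r_i + r_j − tolerance."""
    params = params or ClashParams()
    if len(setA) == 0 or len(setB) == 0:
        raise NrxGeomError("both atom sets must be non-empty")
    hits = _clash_pairs(setA, setB, params.overlap_tolerance, params.neighbor_exclusion)
    return sorted(
        (Clash(setA.labels[i], setB.labels[j], d, o) for i, j, d, o in hits),
        key=lambda c: -c.overlap,
    )


def rotate_about_axis(
    coords: np.ndarray, pivot_point: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rodrigues rotation of coords about the line (pivot_point, axis)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise DegenerateInputError("rotation axis has zero length")
    if abs(norm - 1.0) > 1e-9:
        raise DegenerateInputError("rotation axis must be a unit vector")
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    pivot_point = np.asarray(pivot_point, dtype=float)
    return rot.apply(np.asarray(coords, dtype=float) - pivot_point) + pivot_point


@dataclass
class HingeScanResult:
    pivot: np.ndarray
    axes_sampled: int
    angle_grid: np.ndarray  # degrees
    min_relief_angle: float | None  # degrees; None = not found
    best_axis: np.ndarray | None
    clash_count_by_angle: dict[float, int]  # min over axes at each angle
    initial_clashes: int = 0
    residual_clashes: int | None = None  # minimal count when not found

    @property
    def found(self) -> bool:
        return self.min_relief_angle is not None


def _count_clashes(coords_a, radii_a, labels_a, static_tree, setB, tol, neighbor_exclusion, stop_at=None):
    max_cut = float(radii_a.max() + setB.radii.max() - tol)
    count = 0
    candidates = static_tree.query_ball_point(coords_a, max_cut)
    for i, js in enumerate(candidates):
        if not js:
            continue
        js = np.asarray(js)
        d = np.linalg.norm(setB.coords[js] - coords_a[i], axis=1)
        cut = radii_a[i] + setB.radii[js] - tol
        viol = js[d < cut]
        if len(viol):
            ca, na, _ = labels_a[i]
            for j in viol:
                cb, nb, _ = setB.labels[int(j)]
                if ca == cb and abs(na - nb) <= neighbor_exclusion:
                    continue
                count += 1
                if stop_at is not None and count >= stop_at:
                    return count
    return count


def min_relief_rotation(
    mobile: AtomSet,
    static: AtomSet,
    pivot_point: np.ndarray,
    params: ClashParams | None = None,
    axis_samples: int = 200,
    angle_max: float = 60.0,
    angle_step: float = 1.0,
) -> HingeScanResult:
    """Smallest pivot rotation (over sampled axes) with zero clashes.

    Axes are ``axis_samples`` Fibonacci-sphere directions through
    ``pivot_point``; angles run from ``angle_step`` to ``angle_max``
    in steps of ``angle_step``.  A clash-free input reports 0°.  When
    no grid point relieves every clash the result carries the minimal
    residual clash count instead.
    """
    params = params or ClashParams()
    pivot_point = np.asarray(pivot_point, dtype=float)
    static_tree = cKDTree(static.coords)
    tol = params.overlap_tolerance
    nex = params.neighbor_exclusion

    initial = _count_clashes(
        mobile.coords, mobile.radii, mobile.labels, static_tree, static, tol, nex
    )
    angles = np.arange(angle_step, angle_max + angle_step / 2, angle_step)
    if initial == 0:
        return HingeScanResult(
            pivot=pivot_point,
            axes_sampled=axis_samples,
            angle_grid=angles,
            min_relief_angle=0.0,
            best_axis=None,
            clash_count_by_angle={},
            initial_clashes=0,
        )

    axes = sphere_points(axis_samples)
    centered = mobile.coords - pivot_point
    by_angle: dict[float, int] = {}
    best_overall: int | None = None
    for angle in angles:
        best_at_angle: int | None = None
        for axis in axes:
            rot = Rotation.from_rotvec(np.radians(angle) * axis)
            moved = rot.apply(centered) + pivot_point
            count = _count_clashes(
                moved, mobile.radii, mobile.labels, static_tree, static, tol, nex,
                stop_at=None if best_at_angle is None else best_at_angle,
            )
            if best_at_angle is None or count < best_at_angle:
                best_at_angle = count
            if count == 0:
                by_angle[float(angle)] = 0
                return HingeScanResult(
                    pivot=pivot_point,
                    axes_sampled=axis_samples,
                    angle_grid=angles,
                    min_relief_angle=float(angle),
                    best_axis=axis.copy(),
                    clash_count_by_angle=by_angle,
                    initial_clashes=initial,
                )
        by_angle[float(angle)] = int(best_at_angle)
        if best_overall is None or best_at_angle < best_overall:
            best_overall = best_at_angle
    return HingeScanResult(
        pivot=pivot_point,
        axes_sampled=axis_samples,
        angle_grid=angles,
        min_relief_angle=None,
        best_axis=None,
        clash_count_by_angle=by_angle,
        initial_clashes=initial,
        residual_clashes=best_overall,
    )
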