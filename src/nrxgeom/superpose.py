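"""Rigid-body superposition and RMSD.

Kabsch's SVD solution with the usual determinant correction (the sign
of the smallest singular vector is flipped when the naive optimum is a
reflection), residue correspondences built either from shared author
numbering or from a global sequence alignment, and an iterative
superpose/re-pair refinement for sequence-dissimilar domain pairs —
the route used to compare an LNS domain against a homologue when the
two numbering schemes have nothing in common.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, NrxGeomError
from .model import DomainDefinition, Residue, StructureModel

__all__ = [
    "RigidTransform",
    "Correspondence",
    "kabsch",
    "pair_by_numbering",
    "structure_align",
    "relative_transform",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``x -> R x + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise NrxGeomError("rigid transform needs a 3x3 rotation and a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise NrxGeomError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise NrxGeomError("improper rotation (reflection) rejected")

    @property
    def rotation_angle_deg(self) -> float:
        """Rotation angle in degrees, in [0, 180].

        Equal to acos((trace−1)/2) but evaluated through the rotation
        vector, which keeps full precision near 0° and 180°.
        """
        from scipy.spatial.transform import Rotation

        return math.degrees(Rotation.from_matrix(self.rotation).magnitude())

    @property
    def translation_magnitude(self) -> float:
        return float(np.linalg.norm(self.translation))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform(R, -R @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class Correspondence:
    """Ordered one-to-one residue pairing between two models (via one atom)."""

    pairs: list[tuple[Residue, Residue]]
    atom_name: str = "CA"

    def __post_init__(self) -> None:
        if self.n_matched < 3:
            raise DegenerateInputError(
                f"correspondence has {self.n_matched} pairs; at least 3 required"
            )

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.vstack([p[0].atom(self.atom_name).coord for p in self.pairs])
        b = np.vstack([p[1].atom(self.atom_name).coord for p in self.pairs])
        return a, b


def _check_nondegenerate(x: np.ndarray) -> None:
    if len(x) < 3:
        raise DegenerateInputError(f"need >= 3 points, got {len(x)}")
    centered = x - x.mean(axis=0)
    # rank < 2 <=> all points collinear: rotation about that line is free
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateInputError("points are collinear; superposition is underdetermined")


def kabsch(fixed: np.ndarray, mobile: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``fixed``.

    Returns the transform T minimising RMSD(fixed, T(mobile)) over
    proper rotations and translations, together with that RMSD.
    Reflections are excluded by construction.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise NrxGeomError("coordinate sets must both be (N, 3) with equal N")
    _check_nondegenerate(fixed)
    _check_nondegenerate(mobile)
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    H = (mobile - cm).T @ (fixed - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mobile) - fixed) ** 2, axis=1))))
    return transform, rmsd


def _chain_residues(model: StructureModel, chain: str | None) -> list[Residue]:
    if chain is None:
        if len(model.chains) != 1:
            raise NrxGeomError("model has several chains; specify one")
        chain = next(iter(model.chains))
    if chain not in model.chains:
        raise NrxGeomError(f"chain {chain!r} not in model {model.id!r}")
    return model.chains[chain]


def pair_by_numbering(
    A: StructureModel,
    B: StructureModel,
    atom_name: str = "CA",
    chain_a: str | None = None,
    chain_b: str | None = None,
    residue_range: tuple[int, int] | None = None,
    offset: int = 0,
) -> Correspondence:
    """Pair residues sharing author numbers (B number = A number + offset).

    Only amino-acid residues carrying the requested atom participate.
    ``residue_range`` restricts A-side numbers (inclusive).
    """
    res_a = _chain_residues(A, chain_a)
    res_b = _chain_residues(B, chain_b)
    index_b = {
        r.auth_number: r
        for r in res_b
        if r.category == "amino_acid" and r.atom(atom_name) is not None and not r.icode
    }
    pairs = []
    for ra in res_a:
        if ra.category != "amino_acid" or ra.atom(atom_name) is None or ra.icode:
            continue
        if residue_range and not (residue_range[0] <= ra.auth_number <= residue_range[1]):
            continue
        rb = index_b.get(ra.auth_number + offset)
        if rb is not None:
            pairs.append((ra, rb))
    if not pairs:
        raise NrxGeomError("no shared residue numbers between the two models")
    return Correspondence(pairs, atom_name)


def _sequence_seed_pairs(res_a: list[Residue], res_b: list[Residue]) -> list[tuple[Residue, Residue]]:
    """Seed pairing from a global alignment of the one-letter sequences."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    seq_a = "".join(r.one_letter() for r in res_a).replace("X", "A")
    seq_b = "".join(r.one_letter() for r in res_b).replace("X", "A")
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((res_a[i], res_b[j]))
    return pairs


@dataclass
class AlignmentResult:
    correspondence: Correspondence
    transform: RigidTransform
    rmsd: float
    n_iter: int
    converged: bool
    rmsd_history: list[float] = field(default_factory=list)


def structure_align(
    A: StructureModel,
    B: StructureModel,
    seed: str = "sequence",
    prune_cutoff: float = 4.5,
    max_iter: int = 50,
    atom_name: str = "CA",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> AlignmentResult:
    """Iteratively refined superposition of B onto A.

    Starting from a seed pairing (``sequence``: global alignment with
    BLOSUM62; ``numbering``: shared author numbers), the loop
    superposes on the current pairs, re-pairs mutually nearest Cα
    atoms within ``prune_cutoff`` Å, and repeats until the pair set is
    stable.  RMSD is non-increasing across accepted iterations: an
    iterate that would raise it terminates the loop and the previous
    iterate is returned.
    """
    res_a = [r for r in _chain_residues(A, chain_a) if r.category == "amino_acid" and r.atom(atom_name)]
    res_b = [r for r in _chain_residues(B, chain_b) if r.category == "amino_acid" and r.atom(atom_name)]
    if len(res_a) < 20 or len(res_b) < 20:
        raise DegenerateInputError("structure_align needs >= 20 matched-atom residues per side")
    if seed == "sequence":
        pairs = _sequence_seed_pairs(res_a, res_b)
    elif seed == "numbering":
        pairs = pair_by_numbering(A, B, atom_name, chain_a, chain_b).pairs
    else:
        raise NrxGeomError(f"unknown seed method {seed!r}")
    if len(pairs) < 3:
        raise DegenerateInputError("fewer than 3 seed pairs found")

    xa = np.vstack([r.atom(atom_name).coord for r in res_a])
    xb = np.vstack([r.atom(atom_name).coord for r in res_b])
    ia = {id(r): i for i, r in enumerate(res_a)}
    ib = {id(r): i for i, r in enumerate(res_b)}

    def solve(pr):
        f = xa[[ia[id(a)] for a, _ in pr]]
        m = xb[[ib[id(b)] for _, b in pr]]
        return kabsch(f, m)

    transform, rmsd = solve(pairs)
    history = [rmsd]
    best = (pairs, transform, rmsd)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = transform.apply(xb)
        tree_a, tree_b = cKDTree(xa), cKDTree(moved)
        da, ja = tree_b.query(xa, distance_upper_bound=prune_cutoff)
        db, jb = tree_a.query(moved, distance_upper_bound=prune_cutoff)
        new_pairs = []
        for i in range(len(res_a)):
            j = ja[i]
            if j < len(res_b) and jb[j] == i:  # mutual nearest neighbours
                new_pairs.append((res_a[i], res_b[j]))
        # ties broken deterministically by A-side residue order (ascending number)
        if len(new_pairs) < 3:
            break
        new_transform, new_rmsd = solve(new_pairs)
        same = len(new_pairs) == len(best[0]) and all(
            a is pa and b is pb for (a, b), (pa, pb) in zip(new_pairs, best[0])
        )
        if new_rmsd > best[2] + 1e-12 and len(new_pairs) <= len(best[0]):
            break
        best = (new_pairs, new_transform, new_rmsd)
        history.append(new_rmsd)
        transform = new_transform
        if same:
            converged = True
            break
    pairs, transform, rmsd = best
    return AlignmentResult(
        correspondence=Correspondence(pairs, atom_name),
        transform=transform,
        rmsd=rmsd,
        n_iter=it,
        converged=converged,
        rmsd_history=history,
    )


def relative_transform(T_A: RigidTransform, T_B: RigidTransform) -> RigidTransform:
    """The transform carrying T_A's frame onto T_B's: ``T_B ∘ T_A⁻¹``."""
    return T_B.compose(T_A.inverse())
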