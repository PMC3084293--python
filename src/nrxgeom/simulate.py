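"""Seeded synthetic-structure generators with recorded ground truth.

Every generator is a pure function of its explicit parameters and
seed (single ``numpy.random.Generator`` stream per call, no global
state), returns both the synthetic input and an independently computed
ground truth sidecar, and emits only legal PDB residue/atom codes so
its output survives a round trip through the structure reader.

These objects emulate the *geometry* of multidomain protein problems —
controllable inter-domain contact, designed clashes with known relief
rotations, ideal/perturbed metal shells, sequence sets with a chosen
signature fraction — not realistic folds, density or chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import NrxGeomError
from .model import Atom, DomainDefinition, Residue, StructureModel
from .sasa import SasaParams, residue_sasa
from .clash import ClashParams

__all__ = [
    "make_two_domain_toy",
    "make_clash_scene",
    "make_metal_site",
    "make_egf_set",
    "make_complex_scene",
    "make_plasticity_set",
    "write_fasta",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _blob_residues(
    rng: np.random.Generator,
    n: int,
    center: np.ndarray,
    radius: float,
    start_number: int,
    min_sep: float = 3.2,
) -> list[Residue]:
    """n single-atom GLY 'residues' packed into a sphere, no two closer
    than min_sep (rejection sampling, deterministic under the rng)."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 200_000:
            raise NrxGeomError(
                f"cannot pack {n} points at {min_sep} Å separation into radius {radius} Å"
            )
        p = center + rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p - center) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.vstack(pts) - p, axis=1)) < min_sep:
            continue
        pts.append(p)
    return [
        Residue(
            auth_number=start_number + i,
            name="GLY",
            atoms=[Atom(name="CA", element="C", coord=p)],
        )
        for i, p in enumerate(pts)
    ]


def make_two_domain_toy(
    seed: int,
    separation: float,
    n_per_domain: int = 25,
    domain_radius: float = 7.0,
) -> tuple[StructureModel, dict[str, Any]]:
    """Two pseudo-domains at a controlled centroid separation.

    Ground-truth buried area comes from a 10,000-point SASA evaluation
    (high-density oracle), not from an assumption about contact.
    """
    if separation < 0:
        raise NrxGeomError("separation must be >= 0")
    rng = _rng(seed)
    res_a = _blob_residues(rng, n_per_domain, np.zeros(3), domain_radius, 1)
    res_b = _blob_residues(
        rng, n_per_domain, np.array([separation, 0.0, 0.0]), domain_radius, 1001
    )
    model = StructureModel(id=f"two_domain_s{seed}", chains={"A": res_a, "B": res_b})
    dom_a = DomainDefinition("domA", "A", 1, n_per_domain)
    dom_b = DomainDefinition("domB", "B", 1001, 1000 + n_per_domain)

    dense = SasaParams(n_points=10_000)
    sasa_a = sum(residue_sasa(StructureModel(id="a", chains={"A": res_a}), dense).values())
    sasa_b = sum(residue_sasa(StructureModel(id="b", chains={"B": res_b}), dense).values())
    sasa_ab = sum(residue_sasa(model, dense).values())
    truth = {
        "buried_total_oracle": sasa_a + sasa_b - sasa_ab,
        "oracle_n_points": 10_000,
        "domain_a": dom_a,
        "domain_b": dom_b,
        "separation": separation,
    }
    return model, truth


def _single_atom_model(id: str, chain: str, number: int, coord, name="CA", res="GLY") -> StructureModel:
    return StructureModel(
        id=id,
        chains={chain: [Residue(auth_number=number, name=res,
                                atoms=[Atom(name=name, element="C", coord=np.asarray(coord, float))])]},
    )


def analytic_relief_angle(
    d: float, D: float, contact: float, alpha0: float = 0.0
) -> float:
    """Exact minimal pivot rotation for a one-atom mobile set.

    The mobile atom sits at distance ``d`` from the pivot, the static
    atom at distance ``D``, with angle ``alpha0`` (radians) between
    them at the pivot.  Rotating the mobile atom away from the static
    one in their common plane is optimal; the separation after an
    extra angle θ follows the law of cosines, so the smallest clash-free
    rotation solves d² + D² − 2 d D cos(α₀+θ) = contact².  Degrees.
    """
    c = (d * d + D * D - contact * contact) / (2 * d * D)
    if c > 1.0:
        raise NrxGeomError("scene is geometrically unrelievable (contact unreachable)")
    theta_total = math.acos(max(-1.0, c))
    return max(0.0, math.degrees(theta_total) - math.degrees(alpha0))


def make_clash_scene(
    seed: int,
    kind: str = "single_atom",
    arm_length: float = 8.0,
    gap: float = -0.5,
    n_mobile: int = 5,
    params: ClashParams | None = None,
) -> dict[str, Any]:
    """A designed clash with a known minimal relief rotation.

    ``single_atom``: one mobile C atom at ``arm_length`` from the
    pivot (origin) and one static C atom beyond it, separated by
    contact+``gap`` (gap < 0 ⇒ clash); the minimal relief angle is the
    closed-form law-of-cosines solution recorded in the sidecar.

    ``multi``: a small rigid mobile cluster against a static cluster;
    the sidecar records an independent brute-force (all-pairs, plain
    numpy) grid-search oracle angle on the same axis/angle grid the
    scanner uses.
    """
    params = params or ClashParams()
    rng = _rng(seed)
    r_c = params.radius_of("C")
    contact = 2 * r_c - params.overlap_tolerance
    if kind == "single_atom":
        if gap >= 0:
            # pre-separated: no clash, relief angle 0
            D = arm_length + contact + gap
            truth_angle = 0.0
        else:
            s = contact + gap
            if s <= 0:
                raise NrxGeomError("gap too deep: static atom would sit inside the pivot arm")
            D = arm_length + s
            truth_angle = analytic_relief_angle(arm_length, D, contact)
        mobile = _single_atom_model(f"mob_s{seed}", "M", 100, [arm_length, 0, 0])
        static = _single_atom_model(f"sta_s{seed}", "S", 900, [D, 0, 0])
        return {
            "mobile": mobile,
            "static": static,
            "pivot": np.zeros(3),
            "analytic_angle": truth_angle,
            "params": params,
        }
    if kind != "multi":
        raise NrxGeomError(f"unknown clash scene kind {kind!r}")

    # rigid mobile cluster at the end of an arm; static cluster placed to
    # overlap it slightly
    local = rng.uniform(-1.5, 1.5, (n_mobile, 3))
    mob_pts = local + np.array([arm_length, 0.0, 0.0])
    sta_pts = local * 0.8 + np.array([arm_length + contact + gap, 0.0, 0.0]) + rng.uniform(-0.5, 0.5, (n_mobile, 3))
    mobile = StructureModel(
        id=f"mob_s{seed}",
        chains={"M": [Residue(100 + i, "GLY", [Atom("CA", "C", p)]) for i, p in enumerate(mob_pts)]},
    )
    static = StructureModel(
        id=f"sta_s{seed}",
        chains={"S": [Residue(900 + i, "GLY", [Atom("CA", "C", p)]) for i, p in enumerate(sta_pts)]},
    )
    oracle = _brute_force_relief(mob_pts, sta_pts, np.zeros(3), contact)
    return {
        "mobile": mobile,
        "static": static,
        "pivot": np.zeros(3),
        "oracle_angle": oracle,
        "params": params,
    }


def _fibonacci_axes(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _brute_force_relief(
    mob: np.ndarray,
    sta: np.ndarray,
    pivot: np.ndarray,
    contact: float,
    axis_samples: int = 200,
    angle_max: float = 60.0,
    angle_step: float = 1.0,
) -> float | None:
    """Independent all-pairs grid-search oracle (no KD-tree, explicit
    Rodrigues formula) for the minimal clash-free rotation."""

    def n_clash(pts):
        d = np.linalg.norm(pts[:, None, :] - sta[None, :, :], axis=2)
        return int(np.sum(d < contact))

    if n_clash(mob) == 0:
        return 0.0
    centered = mob - pivot
    axes = _fibonacci_axes(axis_samples)
    for angle in np.arange(angle_step, angle_max + angle_step / 2, angle_step):
        th = math.radians(angle)
        for k in axes:
            # Rodrigues: v cosθ + (k×v) sinθ + k (k·v)(1−cosθ)
            rotated = (
                centered * math.cos(th)
                + np.cross(np.broadcast_to(k, centered.shape), centered) * math.sin(th)
                + np.outer(centered @ k, k) * (1.0 - math.cos(th))
            )
            if n_clash(rotated + pivot) == 0:
                return float(angle)
    return None


def make_metal_site(
    seed: int,
    geometry: str = "octahedral",
    noise_deg: float = 0.0,
    bond_length: float = 2.4,
) -> tuple[StructureModel, dict[str, Any]]:
    """A Ca²⁺ ion with an ideal or angularly perturbed O-ligand shell.

    Ligands are water oxygens at ``bond_length`` Å along the template
    directions, each tilted by an angle drawn uniformly from
    [0, noise_deg] about a random perpendicular axis.
    """
    from .metal import octahedron_vertices, pentagonal_bipyramid_vertices

    rng = _rng(seed)
    if geometry == "octahedral":
        template = octahedron_vertices()
    elif geometry == "pentagonal_bipyramid":
        template = pentagonal_bipyramid_vertices()
    else:
        raise NrxGeomError(f"unknown geometry template {geometry!r}")
    dirs = []
    for v in template:
        if noise_deg > 0:
            tilt = math.radians(rng.uniform(0.0, noise_deg))
            # random unit vector perpendicular to v
            raw = rng.normal(size=3)
            perp = raw - (raw @ v) * v
            perp /= np.linalg.norm(perp)
            v = math.cos(tilt) * v + math.sin(tilt) * perp
        dirs.append(v / np.linalg.norm(v))
    dirs = np.vstack(dirs)
    ion = Residue(500, "CA", [Atom("CA", "CA", np.zeros(3), is_hetero=True)])
    waters = [
        Residue(600 + i, "HOH", [Atom("O", "O", bond_length * v, is_hetero=True)])
        for i, v in enumerate(dirs)
    ]
    model = StructureModel(id=f"metal_{geometry}_s{seed}", chains={"M": [ion] + waters})
    truth = {
        "geometry": geometry,
        "directions": dirs,
        "noise_deg": noise_deg,
        "bond_length": bond_length,
        "ion": ("M", 500),
    }
    return model, truth


def make_egf_set(
    seed: int,
    n_sequences: int = 100,
    signature_fraction: float = 0.03,
    n_decoys: int = 0,
    length: int = 45,
) -> tuple[list[tuple[str, str]], dict[str, Any]]:
    """Random EGF-like sequences with an exact signature-Trp count.

    Each valid sequence carries exactly six cysteines; a chosen number
    have 'W' at the C3+4 position and the rest are guaranteed not to.
    ``n_decoys`` extra sequences carry only five cysteines (register
    failures).  Ground truth records which ids are signature-positive.
    """
    rng = _rng(seed)
    n_signature = round(n_sequences * signature_fraction)
    background = _AA20.replace("C", "").replace("W", "")

    def random_seq(n_cys: int, with_signature: bool, tag: str, idx: int):
        while True:
            # choose cys positions with >= 3 spacing so C3+4 is unambiguous
            pos = np.sort(rng.choice(np.arange(2, length - 6), size=n_cys, replace=False))
            if np.all(np.diff(pos) >= 5):
                break
        seq = list(rng.choice(list(background), size=length))
        for p in pos:
            seq[p] = "C"
        if n_cys >= 3:
            sig = pos[2] + 4
            seq[sig] = "W" if with_signature else "L"
        return f"{tag}_{idx:04d}", "".join(seq)

    records = []
    truth_positive = []
    for i in range(n_sequences):
        positive = i < n_signature
        sid, seq = random_seq(6, positive, "egf", i)
        records.append((sid, seq))
        if positive:
            truth_positive.append(sid)
    for i in range(n_decoys):
        records.append(random_seq(5, False, "decoy", i))
    # deterministic shuffle so positives are not clustered at the front
    order = rng.permutation(len(records))
    records = [records[int(k)] for k in order]
    truth = {
        "n_sequences": n_sequences,
        "n_decoys": n_decoys,
        "n_signature": n_signature,
        "signature_ids": sorted(truth_positive),
        "fraction_of_valid": n_signature / n_sequences if n_sequences else float("nan"),
    }
    return records, truth


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def _helix_residues(start_number: int, n: int, origin: np.ndarray, direction: np.ndarray) -> list[Residue]:
    """An idealized Cα helix marching along ``direction`` from ``origin``."""
    direction = direction / np.linalg.norm(direction)
    # build an orthonormal frame
    ref = np.array([0.0, 0.0, 1.0]) if abs(direction[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    out = []
    for i in range(n):
        ang = math.radians(100.0) * i
        p = origin + 1.5 * i * direction + 2.3 * (math.cos(ang) * u + math.sin(ang) * v)
        out.append(Residue(start_number + i, "ALA", [Atom("CA", "C", p)]))
    return out


def make_complex_scene(seed: int, relief_gap: float = -0.8) -> dict[str, Any]:
    """A two-molecule docking scene with a designed arm clash.

    The "alpha" molecule is an arm (residues 100–129) joined at a
    pivot residue 150 to a core helix (residues 200–239).  The
    "complex" contains an exact copy of the core (chain R, same
    numbering) carried by a known rigid motion, plus a receptor blob
    (chain N) positioned so the superposed arm clashes with it.  The
    sidecar records the superposition truth and a brute-force oracle
    relief angle about the pivot.
    """
    rng = _rng(seed)
    params = ClashParams()
    pivot = np.zeros(3)
    arm = _helix_residues(100, 30, pivot + np.array([-3.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]))
    pivot_res = Residue(150, "PRO", [Atom("CA", "C", pivot)])
    core = _helix_residues(200, 40, pivot + np.array([3.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    alpha = StructureModel(id=f"alpha_s{seed}", chains={"A": arm + [pivot_res] + core})

    # known rigid motion carrying the core into the complex frame
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    t = rng.uniform(-20, 20, 3)
    moved_core = [
        Residue(r.auth_number, r.name, [Atom("CA", "C", R @ r.atoms[0].coord + t)])
        for r in core
    ]
    # receptor blob placed against the arm's mid-section (in complex frame)
    arm_mid = R @ arm[15].atoms[0].coord + t
    r_c = params.radius_of("C")
    contact = 2 * r_c - params.overlap_tolerance
    blob_center = arm_mid + np.array([0.0, contact + relief_gap, 0.0])
    blob = _blob_residues(rng, 12, blob_center, 6.0, 900, min_sep=3.2)
    complex_model = StructureModel(
        id=f"complex_s{seed}", chains={"R": moved_core, "N": blob}
    )

    arm_pts = np.vstack([R @ r.atoms[0].coord + t for r in arm])
    sta_pts = np.vstack([r.atoms[0].coord for r in blob])
    pivot_in_complex = R @ pivot + t
    oracle = _brute_force_relief(arm_pts, sta_pts, pivot_in_complex, contact)
    return {
        "alpha": alpha,
        "complex": complex_model,
        "rotation": R,
        "translation": t,
        "oracle_angle": oracle,
        "pivot_residue": ("A", 150),
        "core_range": (200, 239),
        "arm_range": (100, 130),
        "params": params,
    }


def make_plasticity_set(
    seed: int,
    rotations_deg: tuple[float, ...] = (0.0, 3.0, 5.0),
    translations: tuple[float, ...] = (0.0, 0.0, 0.0),
) -> dict[str, Any]:
    """Complex instances whose ligand-domain placement differs by known
    rotations/translations after receptor superposition.

    Instance i carries the mobile helix (chain R) rotated by
    ``rotations_deg[i]`` about a fixed axis through the helix centroid
    (so rotation does not move the centroid) and translated by
    ``translations[i]`` along a fixed direction; each whole instance is
    then scrambled by a random global rigid motion that receptor
    superposition must undo.  Pairwise ground truths are
    |aᵢ − aⱼ| degrees and |tᵢ − tⱼ| Å.
    """
    from scipy.spatial.transform import Rotation

    if len(rotations_deg) != len(translations):
        raise NrxGeomError("rotations and translations must be the same length")
    rng = _rng(seed)
    receptor = _blob_residues(rng, 60, np.zeros(3), 14.0, 1, min_sep=3.6)
    helix = _helix_residues(300, 40, np.array([25.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    helix_pts = np.vstack([r.atoms[0].coord for r in helix])
    centroid = helix_pts.mean(axis=0)
    axis = np.array([0.0, 0.0, 1.0])
    shift_dir = np.array([0.0, 1.0, 0.0])

    instances = []
    for a_deg, t_mag in zip(rotations_deg, translations):
        Q = Rotation.from_rotvec(math.radians(a_deg) * axis).as_matrix()
        pts = (helix_pts - centroid) @ Q.T + centroid + t_mag * shift_dir
        # global scramble
        G = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        g = rng.uniform(-30, 30, 3)
        rec = [
            Residue(r.auth_number, r.name, [Atom("CA", "C", G @ r.atoms[0].coord + g)])
            for r in receptor
        ]
        hel = [
            Residue(r.auth_number, r.name, [Atom("CA", "C", G @ p + g)])
            for r, p in zip(helix, pts)
        ]
        instances.append(
            StructureModel(id=f"inst_{a_deg}_{t_mag}", chains={"L": rec, "R": hel})
        )
    n = len(instances)
    rot_truth = np.zeros((n, n))
    tr_truth = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            rot_truth[i, j] = abs(rotations_deg[i] - rotations_deg[j])
            tr_truth[i, j] = abs(translations[i] - translations[j])
    return {
        "instances": instances,
        "nl_chain": "L",
        "nrx_chain": "R",
        "lns6_range": (300, 339),
        "pairwise_rotation_truth": rot_truth,
        "pairwise_translation_truth": tr_truth,
    }
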