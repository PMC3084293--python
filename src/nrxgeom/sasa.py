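"""Solvent-accessible surface area (Shrake–Rupley) and buried interfaces.

The accessible surface of an atom is the sphere of radius r_vdw +
r_probe; its area is estimated by scattering a deterministic
golden-spiral point set on that sphere and counting the fraction of
points not swallowed by any neighbour's expanded sphere.  Buried area
between two domains is the usual two-sided measure

    ΔASA = SASA(A) + SASA(B) − SASA(A ∪ B)

computed over amino-acid heavy atoms, with linkage residues optionally
excluded from every term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import MissingRadiusError, NrxGeomError
from .model import DomainDefinition, StructureModel, select_domain

__all__ = [
    "DEFAULT_RADII",
    "SasaParams",
    "InterfaceReport",
    "sphere_points",
    "sasa",
    "total_sasa",
    "residue_sasa",
    "buried_interface_area",
    "residue_exposure_ratio",
]

# Fixed van der Waals radii (Å) by element.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
    "CA": 1.97,  # calcium ion
    "H": 1.20,
}


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise NrxGeomError("probe radius must be positive")
        if self.n_points < 92:
            raise NrxGeomError("n_points must be >= 92 for a usable sphere sample")

    def radius_of(self, element: str, atom_name: str = "") -> float:
        key = element.strip().upper()
        if key not in self.radii_table:
            raise MissingRadiusError(
                f"no van der Waals radius for atom {atom_name or '?'} (element {element!r})"
            )
        return self.radii_table[key]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral sample of the unit sphere, (n, 3)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _gather(model: StructureModel, params: SasaParams):
    coords, radii, owners = [], [], []
    for cid, res, atom in model.atoms():
        coords.append(atom.coord)
        radii.append(params.radius_of(atom.element, atom.name))
        owners.append((cid, res.auth_number, res.icode))
    if not coords:
        raise NrxGeomError("model has no atoms to compute SASA for")
    return np.vstack(coords), np.asarray(radii), owners


def sasa(model: StructureModel, params: SasaParams | None = None) -> np.ndarray:
    """Per-atom solvent-accessible area, Å², in model atom order."""
    params = params or SasaParams()
    coords, radii, _ = _gather(model, params)
    return _sasa_arrays(coords, radii, params)


def _sasa_arrays(coords: np.ndarray, radii: np.ndarray, params: SasaParams) -> np.ndarray:
    n = len(coords)
    expanded = radii + params.probe_radius
    unit = sphere_points(params.n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        neigh = tree.query_ball_point(coords[i], ri + expanded.max())
        neigh = [j for j in neigh if j != i]
        exposed = np.ones(params.n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * np.pi * ri * ri
    return areas


def total_sasa(model: StructureModel, params: SasaParams | None = None) -> float:
    return float(sasa(model, params).sum())


def residue_sasa(model: StructureModel, params: SasaParams | None = None) -> dict[tuple[str, int, str], float]:
    """SASA aggregated per residue, keyed by (chain, auth_number, icode)."""
    params = params or SasaParams()
    coords, radii, owners = _gather(model, params)
    areas = _sasa_arrays(coords, radii, params)
    out: dict[tuple[str, int, str], float] = {}
    for key, a in zip(owners, areas):
        out[key] = out.get(key, 0.0) + float(a)
    return out


@dataclass
class InterfaceReport:
    """Two-sided buried area between two domain selections."""

    buried_total: float
    buried_per_residue: dict[tuple[str, int, str], float]
    excluded_residues: list[int]
    domain_a: str = ""
    domain_b: str = ""

    def __post_init__(self) -> None:
        s = sum(self.buried_per_residue.values())
        if abs(s - self.buried_total) > 1e-6 * max(1.0, abs(self.buried_total)):
            raise NrxGeomError("per-residue buried areas do not sum to the total")


def _merge(a: StructureModel, b: StructureModel, id: str) -> StructureModel:
    chains: dict[str, list] = {}
    for m in (a, b):
        for cid, residues in m.chains.items():
            chains.setdefault(cid, []).extend(residues)
    return StructureModel(id=id, chains=chains)


def _drop_residues(model: StructureModel, exclude: set[int]) -> StructureModel:
    chains = {
        cid: [r for r in residues if r.auth_number not in exclude]
        for cid, residues in model.chains.items()
    }
    chains = {c: r for c, r in chains.items() if r}
    if not chains:
        raise NrxGeomError("exclusion list removed every residue")
    return StructureModel(id=model.id, chains=chains)


def buried_interface_area(
    model: StructureModel,
    domA: DomainDefinition,
    domB: DomainDefinition,
    exclude: list[int] | None = None,
    params: SasaParams | None = None,
) -> InterfaceReport:
    """Buried ASA between two disjoint domains of one model.

    ``exclude`` lists author residue numbers removed from both the
    isolated and the combined calculations — used for residues that
    form the covalent domain linkage and would otherwise masquerade as
    interface.  Amino-acid heavy atoms only.
    """
    if domA.chain == domB.chain and not (domA.end < domB.start or domB.end < domA.start):
        raise NrxGeomError(f"domains {domA.name} and {domB.name} overlap")
    params = params or SasaParams()
    excl = set(exclude or [])
    a = select_domain(model, domA, categories=("amino_acid",))
    b = select_domain(model, domB, categories=("amino_acid",))
    if excl:
        a = _drop_residues(a, excl)
        b = _drop_residues(b, excl)
    ab = _merge(a, b, id=f"{a.id}+{b.id}")
    sasa_a = residue_sasa(a, params)
    sasa_b = residue_sasa(b, params)
    sasa_ab = residue_sasa(ab, params)
    per_res: dict[tuple[str, int, str], float] = {}
    for alone in (sasa_a, sasa_b):
        for key, area in alone.items():
            per_res[key] = area - sasa_ab[key]
    total = float(sum(per_res.values()))
    return InterfaceReport(
        buried_total=total,
        buried_per_residue=per_res,
        excluded_residues=sorted(excl),
        domain_a=domA.name,
        domain_b=domB.name,
    )


def residue_exposure_ratio(
    model: StructureModel,
    target_residues: list[int],
    context_domain: DomainDefinition,
    params: SasaParams | None = None,
) -> dict[int, float | None]:
    """Per-residue SASA ratio: full model vs isolated context domain.

    A ratio near 1 means the rest of the model leaves the residue as
    exposed as it is in the isolated domain.  Residues with zero
    isolated SASA map to ``None`` (undefined).
    """
    params = params or SasaParams()
    for n in target_residues:
        if not context_domain.contains(n):
            raise NrxGeomError(f"residue {n} outside context domain {context_domain.name}")
    iso = select_domain(model, context_domain, categories=("amino_acid",))
    protein_chains = {
        cid: [r for r in residues if r.category == "amino_acid"]
        for cid, residues in model.chains.items()
    }
    protein = StructureModel(id=model.id, chains={c: r for c, r in protein_chains.items() if r})
    sasa_iso = residue_sasa(iso, params)
    sasa_full = residue_sasa(protein, params)
    out: dict[int, float | None] = {}
    for n in target_residues:
        key = (context_domain.chain, n, "")
        denom = sasa_iso.get(key, 0.0)
        out[n] = None if denom <= 1e-9 else sasa_full.get(key, 0.0) / denom
    return out
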