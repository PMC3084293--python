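"""End-to-end complex modelling and interface-plasticity analysis.

``model_complex`` reproduces the docking thought-experiment for a
multidomain fragment: superpose its receptor-binding domain onto the
corresponding domain of a known complex, count the steric clashes the
extra domains make with the partner, and, when they clash, find the
smallest pivot rotation of the offending segment that clears them.

``plasticity_analysis`` measures how much a bound domain's placement
varies across independent copies of the same complex: all copies are
superposed on the partner molecule, and every pair is compared by the
rigid transform between their bound-domain Cα sets (rotation angle and
centroid displacement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clash import AtomSet, Clash, ClashParams, HingeScanResult, atom_set, detect_clashes, min_relief_rotation, rotate_about_axis
from .errors import NrxGeomError
from .model import Atom, Residue, StructureModel
from .superpose import Correspondence, RigidTransform, kabsch, pair_by_numbering

__all__ = [
    "ComplexSpec",
    "ComplexModelReport",
    "ComplexInstance",
    "PlasticityReport",
    "transform_model",
    "model_complex",
    "plasticity_analysis",
]


def transform_model(model: StructureModel, T: RigidTransform) -> StructureModel:
    """A copy of the model with every coordinate carried by T."""
    chains = {}
    for cid, residues in model.chains.items():
        chains[cid] = [
            replace(
                r,
                atoms=[replace(a, coord=T.apply(a.coord[None, :])[0]) for a in r.atoms],
            )
            for r in residues
        ]
    return StructureModel(id=model.id, chains=chains)


@dataclass(frozen=True)
class ComplexSpec:
    """Chain/range mapping for model_complex.

    ``alpha_*`` name the superposition anchor inside the multidomain
    fragment; ``nrx_chain``/``nl_chain`` name the corresponding bound
    domain and the partner molecule in the complex;
    ``numbering_offset`` maps alpha numbering onto the complex's
    (complex number = alpha number + offset); ``mobile_range`` is the
    segment swung about ``pivot`` when clashes appear.
    """

    alpha_chain: str
    anchor_range: tuple[int, int]
    nrx_chain: str
    nl_chain: str
    mobile_range: tuple[int, int]
    pivot_residue: int
    pivot_atom: str = "CA"
    numbering_offset: int = 0
    rmsd_warn_threshold: float = 3.0


@dataclass
class ComplexModelReport:
    superposition_rmsd: float
    n_anchor_residues: int
    initial_clashes: list[Clash]
    hinge: HingeScanResult
    output_model: StructureModel
    rmsd_warning: bool = False

    @property
    def n_initial_clashes(self) -> int:
        return len(self.initial_clashes)


def model_complex(
    alpha: StructureModel,
    complex_model: StructureModel,
    spec: ComplexSpec,
    clash_params: ClashParams | None = None,
    axis_samples: int = 200,
    angle_max: float = 60.0,
    angle_step: float = 1.0,
) -> ComplexModelReport:
    """Superpose, count clashes, relieve by pivot rotation, merge.

    Deterministic end to end: the only search is over the fixed
    axis/angle grid of the hinge scan.
    """
    clash_params = clash_params or ClashParams()
    if spec.nrx_chain not in complex_model.chains:
        raise NrxGeomError(f"complex has no chain {spec.nrx_chain!r}")
    if spec.nl_chain not in complex_model.chains:
        raise NrxGeomError(f"complex has no chain {spec.nl_chain!r}")

    corr = pair_by_numbering(
        alpha,
        complex_model,
        chain_a=spec.alpha_chain,
        chain_b=spec.nrx_chain,
        residue_range=spec.anchor_range,
        offset=spec.numbering_offset,
    )
    alpha_xyz, complex_xyz = corr.coords()
    T, rmsd = kabsch(complex_xyz, alpha_xyz)
    placed = transform_model(alpha, T)

    mobile_set = atom_set(
        placed, clash_params, chain=spec.alpha_chain, residue_range=spec.mobile_range
    )
    static_set = atom_set(complex_model, clash_params, chain=spec.nl_chain)
    clashes = detect_clashes(mobile_set, static_set, clash_params)

    pivot_res = placed.find_residue(spec.alpha_chain, spec.pivot_residue)
    pivot_atom = pivot_res.atom(spec.pivot_atom)
    if pivot_atom is None:
        raise NrxGeomError(
            f"pivot residue {spec.pivot_residue} has no atom {spec.pivot_atom!r}"
        )
    # drop mobile residues covalently adjacent to the pivot (linker guard)
    nex = clash_params.neighbor_exclusion
    keep = [
        i
        for i, (cid, num, _) in enumerate(mobile_set.labels)
        if not (cid == spec.alpha_chain and abs(num - spec.pivot_residue) <= nex)
    ]
    scan_set = AtomSet(
        mobile_set.coords[keep],
        mobile_set.radii[keep],
        [mobile_set.labels[i] for i in keep],
    )
    hinge = min_relief_rotation(
        scan_set,
        static_set,
        pivot_atom.coord,
        clash_params,
        axis_samples=axis_samples,
        angle_max=angle_max,
        angle_step=angle_step,
    )

    # build the merged output: relieved fragment as chain X + the complex
    final = placed
    if hinge.found and hinge.min_relief_angle and hinge.best_axis is not None:
        chains = {}
        for cid, residues in placed.chains.items():
            new_res = []
            for r in residues:
                if cid == spec.alpha_chain and spec.mobile_range[0] <= r.auth_number <= spec.mobile_range[1]:
                    new_res.append(
                        replace(
                            r,
                            atoms=[
                                replace(
                                    a,
                                    coord=rotate_about_axis(
                                        a.coord[None, :],
                                        pivot_atom.coord,
                                        hinge.best_axis,
                                        hinge.min_relief_angle,
                                    )[0],
                                )
                                for a in r.atoms
                            ],
                        )
                    )
                else:
                    new_res.append(r)
            chains[cid] = new_res
        final = StructureModel(id=placed.id, chains=chains)

    merged_chains: dict[str, list[Residue]] = {"X": [r for res in final.chains.values() for r in res]}
    for cid, residues in complex_model.chains.items():
        out_cid = cid if cid != "X" else "Y"
        merged_chains[out_cid] = list(residues)
    merged = StructureModel(id=f"{alpha.id}_on_{complex_model.id}", chains=merged_chains)

    report = ComplexModelReport(
        superposition_rmsd=rmsd,
        n_anchor_residues=corr.n_matched,
        initial_clashes=clashes,
        hinge=hinge,
        output_model=merged,
        rmsd_warning=rmsd > spec.rmsd_warn_threshold,
    )
    if not clashes and hinge.min_relief_angle != 0.0:
        raise NrxGeomError("internal inconsistency: clash-free input with nonzero relief")
    return report


@dataclass(frozen=True)
class ComplexInstance:
    """One excised partner/bound-domain pair."""

    model: StructureModel
    nl_chain: str
    nrx_chain: str
    lns6_range: tuple[int, int]
    label: str = ""
    nl_offset: int = 0  # instance NL number = reference NL number + offset
    nrx_offset: int = 0


@dataclass
class PlasticityReport:
    labels: list[str]
    pairwise_rotation_deg: np.ndarray
    pairwise_translation_A: np.ndarray
    max_rotation: float
    max_translation: float
    n_nl_shared: list[int]


def plasticity_analysis(
    instances: list[ComplexInstance],
    min_shared_nl: int = 50,
) -> PlasticityReport:
    """Pairwise bound-domain deviations after partner superposition.

    Every instance is superposed onto the first via its partner (NL)
    chain Cα atoms; each instance's bound-domain Cα set is carried into
    that common frame; for every pair the Kabsch transform between the
    shared-residue subsets gives the rotation angle, and the centroid
    displacement gives the translation.
    """
    if len(instances) < 2:
        raise NrxGeomError("plasticity analysis needs at least two complex instances")
    ref = instances[0]
    placed_lns6: list[dict[int, np.ndarray]] = []
    n_shared = []
    for inst in instances:
        corr = pair_by_numbering(
            ref.model,
            inst.model,
            chain_a=ref.nl_chain,
            chain_b=inst.nl_chain,
            offset=inst.nl_offset - ref.nl_offset,
        )
        if corr.n_matched < min_shared_nl:
            raise NrxGeomError(
                f"instance {inst.label or inst.model.id}: only {corr.n_matched} shared "
                f"partner residues (< {min_shared_nl})"
            )
        n_shared.append(corr.n_matched)
        fixed, mobile = corr.coords()
        T, _ = kabsch(fixed, mobile)
        coords: dict[int, np.ndarray] = {}
        for r in inst.model.chains[inst.nrx_chain]:
            # canonical numbering shared across instances
            canonical = r.auth_number - inst.nrx_offset
            if (
                r.category == "amino_acid"
                and inst.lns6_range[0] <= r.auth_number <= inst.lns6_range[1]
                and r.atom("CA") is not None
            ):
                coords[canonical] = T.apply(r.atom("CA").coord[None, :])[0]
        if len(coords) < 3:
            raise NrxGeomError(f"instance {inst.label or inst.model.id}: bound domain too small")
        placed_lns6.append(coords)

    n = len(instances)
    rot = np.zeros((n, n))
    trans = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sorted(set(placed_lns6[i]) & set(placed_lns6[j]))
            if len(shared) < 3:
                raise NrxGeomError(f"instances {i} and {j} share too few bound-domain residues")
            xi = np.vstack([placed_lns6[i][k] for k in shared])
            xj = np.vstack([placed_lns6[j][k] for k in shared])
            T, _ = kabsch(xi, xj)
            rot[i, j] = rot[j, i] = T.rotation_angle_deg
            trans[i, j] = trans[j, i] = float(np.linalg.norm(xi.mean(axis=0) - xj.mean(axis=0)))
    labels = [inst.label or inst.model.id for inst in instances]
    return PlasticityReport(
        labels=labels,
        pairwise_rotation_deg=rot,
        pairwise_translation_A=trans,
        max_rotation=float(rot.max()),
        max_translation=float(trans.max()),
        n_nl_shared=n_shared,
    )
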