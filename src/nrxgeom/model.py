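"""Atomic structure models: reading, writing, selection and census.

The in-memory hierarchy is deliberately small — chains of residues of
atoms, indexed by *author* residue numbering (the numbering the
depositors chose, e.g. bovine Nrx1α numbering without splice
insertions).  gemmi does the heavy lifting for PDB/mmCIF I/O; this
module owns the domain types every other module consumes.

Policies applied on read:

* hydrogens are dropped (downstream geometry is heavy-atom only);
* of alternate conformers, the highest-occupancy one is kept, ties
  broken by the alphabetically first altloc, so that every residue is a
  single deterministic conformer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .errors import EmptySelectionError, FormatError, NrxGeomError, ParseError

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "DomainDefinition",
    "ModelCensus",
    "read_structure",
    "select_domain",
    "extract_sequence",
    "model_census",
    "write_pdb",
    "residue_category",
]

# 3-letter -> 1-letter for the 20 standard amino acids.  MSE
# (selenomethionine) is accepted as an amino acid but maps to 'X' in
# extracted sequences, as do all other non-standard residues.
_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AMINO_ACIDS = set(_AA3_TO_1) | {"MSE"}
_WATERS = {"HOH", "WAT", "DOD"}
_IONS = {"CA", "NA", "MG", "ZN", "K", "CL", "MN", "FE"}
_SUGARS = {"NAG", "NDG", "BMA", "MAN", "GAL", "FUC", "GLC", "SIA"}


def residue_category(name: str) -> str:
    """Classify a 3-letter residue code.

    Returns one of ``amino_acid``, ``water``, ``ion``, ``sugar``,
    ``other``.  The table is fixed and intentionally small; unknown
    codes fall through to ``other``.
    """
    name = name.strip().upper()
    if name in _AMINO_ACIDS:
        return "amino_acid"
    if name in _WATERS:
        return "water"
    if name in _IONS:
        return "ion"
    if name in _SUGARS:
        return "sugar"
    return "other"


@dataclass
class Atom:
    """A single heavy atom."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise NrxGeomError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise NrxGeomError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise NrxGeomError(f"atom {self.name}: element symbol is empty")


@dataclass
class Residue:
    """One residue, identified by author number (+ optional insertion code)."""

    auth_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def category(self) -> str:
        return residue_category(self.name)

    @property
    def label(self) -> str:
        """Author number with insertion-code suffix, e.g. ``100A``."""
        return f"{self.auth_number}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def one_letter(self) -> str:
        return _AA3_TO_1.get(self.name.upper(), "X")


@dataclass
class StructureModel:
    """Hierarchical model: chain id -> ordered residues."""

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for cid, residues in self.chains.items():
            for r in residues:
                key = (cid, r.auth_number, r.icode)
                if key in seen:
                    raise NrxGeomError(f"duplicate residue {cid}/{r.label}")
                seen.add(key)

    def residues(self) -> Iterator[tuple[str, Residue]]:
        for cid, residues in self.chains.items():
            for r in residues:
                yield cid, r

    def atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for cid, r in self.residues():
            for a in r.atoms:
                yield cid, r, a

    def n_residues(self) -> int:
        return sum(len(res) for res in self.chains.values())

    def coords(self) -> np.ndarray:
        """All atom coordinates, (N, 3)."""
        pts = [a.coord for _, _, a in self.atoms()]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def find_residue(self, chain: str, auth_number: int, icode: str = "") -> Residue:
        for r in self.chains.get(chain, []):
            if r.auth_number == auth_number and r.icode == icode:
                return r
        raise KeyError(f"residue {chain}/{auth_number}{icode} not in model {self.id!r}")


@dataclass(frozen=True)
class DomainDefinition:
    """Named residue range (inclusive) on one chain, in author numbering."""

    name: str
    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise NrxGeomError(f"domain {self.name}: start {self.start} > end {self.end}")

    def contains(self, auth_number: int) -> bool:
        return self.start <= auth_number <= self.end


@dataclass(frozen=True)
class ModelCensus:
    n_amino_acids: int
    n_waters: int
    n_ions: int
    n_sugars: int
    n_other: int = 0
    ion_identities: tuple[str, ...] = ()


def _pick_conformer(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties go to the alphabetically first altloc."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc or ""))


def _from_gemmi(st: gemmi.Structure) -> StructureModel:
    st.setup_entities()
    chains: dict[str, list[Residue]] = {}
    model = st[0]
    for chain in model:
        cid = chain.name
        out = chains.setdefault(cid, [])
        for res in chain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name in by_name:
                g = _pick_conformer(by_name[name])
                atoms.append(
                    Atom(
                        name=name,
                        element=g.element.name,
                        coord=np.array([g.pos.x, g.pos.y, g.pos.z]),
                        b_factor=g.b_iso,
                        occupancy=min(max(g.occ, 0.0), 1.0),
                        altloc=(g.altloc or "").strip("\x00"),
                        is_hetero=res.het_flag == "H",
                    )
                )
            if atoms:
                out.append(
                    Residue(
                        auth_number=res.seqid.num,
                        name=res.name,
                        atoms=atoms,
                        icode=(res.seqid.icode or "").strip(),
                    )
                )
    chains = {c: r for c, r in chains.items() if r}
    if not chains:
        raise ParseError("structure contains no heavy atoms")
    return StructureModel(id=st.name, chains=chains)


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is one of ``pdb``, ``mmcif`` or ``auto`` (detect by
    extension, falling back to sniffing the first record).  Hydrogens
    are dropped and alternate conformers reduced to one per atom.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.name.lower()
        if suffix.endswith((".cif", ".mmcif", ".cif.gz")):
            fmt = "mmcif"
        elif suffix.endswith((".pdb", ".ent", ".pdb.gz")):
            fmt = "pdb"
        else:
            head = path.read_text(errors="replace")[:2048]
            fmt = "mmcif" if head.lstrip().startswith("data_") else "pdb"
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no model records found")
    m = _from_gemmi(st)
    m.id = m.id or path.stem
    return m


def select_domain(
    model: StructureModel,
    dom: DomainDefinition,
    heavy_only: bool = True,
    categories: Iterable[str] = ("amino_acid",),
) -> StructureModel:
    """Sub-model of residues with ``dom.start <= auth_number <= dom.end``.

    Only residues whose category is in ``categories`` are kept
    (amino acids by default — waters and heteroatoms must be asked for
    explicitly).  Raises :class:`EmptySelectionError` when nothing
    matches.
    """
    if dom.chain not in model.chains:
        raise EmptySelectionError(f"chain {dom.chain!r} not in model {model.id!r}")
    cats = set(categories)
    picked = []
    for r in model.chains[dom.chain]:
        if dom.contains(r.auth_number) and r.category in cats:
            atoms = [a for a in r.atoms if not heavy_only or a.element.upper() != "H"]
            if atoms:
                picked.append(replace(r, atoms=list(atoms)))
    if not picked:
        raise EmptySelectionError(
            f"domain {dom.name} ({dom.chain} {dom.start}-{dom.end}) selects no residues"
        )
    return StructureModel(id=f"{model.id}:{dom.name}", chains={dom.chain: picked})


def extract_sequence(model: StructureModel, dom: DomainDefinition) -> list[tuple[int, str]]:
    """One-letter sequence of the domain, paired with author numbers.

    Non-standard amino acids (including MSE) appear as ``X``.
    """
    sub = select_domain(model, dom, categories=("amino_acid",))
    pairs = [(r.auth_number, r.one_letter()) for r in sub.chains[dom.chain]]
    if not pairs:
        raise EmptySelectionError(f"domain {dom.name}: no amino acids in range")
    return pairs


def model_census(model: StructureModel) -> ModelCensus:
    """Count residues by category (amino acids, waters, ions, sugars)."""
    counts = {"amino_acid": 0, "water": 0, "ion": 0, "sugar": 0, "other": 0}
    ions: list[str] = []
    for _, r in model.residues():
        counts[r.category] += 1
        if r.category == "ion":
            ions.append(r.name.upper())
    return ModelCensus(
        n_amino_acids=counts["amino_acid"],
        n_waters=counts["water"],
        n_ions=counts["ion"],
        n_sugars=counts["sugar"],
        n_other=counts["other"],
        ion_identities=tuple(sorted(ions)),
    )


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id or "model"
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        if len(cid) != 1:
            raise NrxGeomError(f"chain id {cid!r} not encodable in PDB (must be 1 character)")
        gc = gemmi.Chain(cid)
        for r in residues:
            if not -999 <= r.auth_number <= 9999:
                raise NrxGeomError(f"residue number {r.auth_number} not encodable in PDB")
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.auth_number, r.icode or " ")
            gr.het_flag = "H" if (r.category != "amino_acid" or r.atoms[0].is_hetero) else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                ga.altloc = a.altloc[:1] if a.altloc else "\x00"
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-width PDB records."""
    if model.n_residues() == 0:
        raise NrxGeomError("refusing to write an empty model")
    st = _to_gemmi(model)
    st.write_pdb(str(path))
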