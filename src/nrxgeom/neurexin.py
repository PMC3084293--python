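"""Neurexin-specific constants and helpers.

Domain boundaries of the third neurexin repeat (bovine Nrx1α author
numbering, splice insertions excluded): LNS5 867–1045, EGF3 1046–1084,
LNS6 1085–1261.  β-neurexin structures number the same LNS6 sequence
from Gly84 (the shared GTTYIF register starts at α-Gly1086), so
β number = α number − 1002.  Pro1085 at the EGF3–LNS6 junction is the
pivot about which the LNS5+EGF3 arm can swing; Trp1065 in EGF3 is the
signature tryptophan that locks EGF3 onto LNS5.
"""

from __future__ import annotations

import numpy as np

from .errors import NrxGeomError
from .model import DomainDefinition, StructureModel

__all__ = [
    "LNS5_RANGE",
    "EGF3_RANGE",
    "LNS6_RANGE",
    "LNS6_SHARED_RANGE",
    "PIVOT_RESIDUE",
    "SIGNATURE_TRP",
    "BETA_NUMBERING_OFFSET",
    "LINKAGE_RESIDUES",
    "alpha_domains",
    "main_protein_chain",
    "identify_heterodimer_pairs",
]

LNS5_RANGE = (867, 1045)
EGF3_RANGE = (1046, 1084)
LNS6_RANGE = (1085, 1261)
# post-Pro1085 segment shared with β-neurexin (GTTYIF register at 1086)
LNS6_SHARED_RANGE = (1086, 1261)
PIVOT_RESIDUE = 1085
SIGNATURE_TRP = 1065
BETA_NUMBERING_OFFSET = -1002  # β number = α number + offset
# covalent LNS5-EGF3 linkage, excluded from interface burial
LINKAGE_RESIDUES = (1045, 1046)


def main_protein_chain(model: StructureModel, min_residues: int = 200) -> str:
    """The chain carrying the (largest) protein molecule."""
    best, best_n = None, 0
    for cid, residues in model.chains.items():
        n = sum(1 for r in residues if r.category == "amino_acid")
        if n > best_n:
            best, best_n = cid, n
    if best is None or best_n < min_residues:
        raise NrxGeomError(f"no chain with >= {min_residues} amino acids in {model.id!r}")
    return best


def alpha_domains(chain: str) -> dict[str, DomainDefinition]:
    """LNS5 / EGF3 / LNS6 definitions on the given chain."""
    return {
        "LNS5": DomainDefinition("LNS5", chain, *LNS5_RANGE),
        "EGF3": DomainDefinition("EGF3", chain, *EGF3_RANGE),
        "LNS6": DomainDefinition("LNS6", chain, *LNS6_RANGE),
    }


def identify_heterodimer_pairs(
    model: StructureModel, max_nrx_residues: int = 350
) -> list[tuple[str, str]]:
    """(neuroligin chain, neurexin chain) pairs in a 2:2 complex.

    Chains are split by size — an Nrx1β LNS domain is ~180 residues,
    a neuroligin ectodomain ~600 — and each neurexin chain is assigned
    to the neuroligin chain its Cα centroid sits closest to.
    """
    sizes = {
        cid: sum(1 for r in residues if r.category == "amino_acid")
        for cid, residues in model.chains.items()
    }
    nrx = [c for c, n in sizes.items() if 50 <= n <= max_nrx_residues]
    nl = [c for c, n in sizes.items() if n > max_nrx_residues]
    if not nrx or not nl:
        raise NrxGeomError("could not split chains into neurexin-sized and neuroligin-sized")

    def centroid(cid):
        pts = [
            r.atom("CA").coord
            for r in model.chains[cid]
            if r.category == "amino_acid" and r.atom("CA") is not None
        ]
        return np.mean(pts, axis=0)

    def min_dist(ca, cb):
        pa = np.vstack([
            r.atom("CA").coord for r in model.chains[ca]
            if r.category == "amino_acid" and r.atom("CA")
        ])
        pb = np.vstack([
            r.atom("CA").coord for r in model.chains[cb]
            if r.category == "amino_acid" and r.atom("CA")
        ])
        from scipy.spatial import cKDTree

        return float(cKDTree(pa).query(pb)[0].min())

    pairs = []
    for c in sorted(nrx):
        partner = min(sorted(nl), key=lambda l: min_dist(c, l))
        pairs.append((partner, c))
    return pairs
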