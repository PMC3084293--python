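#!/usr/bin/env python
"""Domain-level geometry of the deposited neurexin fragment.

On 3ASI: residue census, the Ca²⁺ site of the LNS6 domain (ligand
shell, roles and coordination geometry), and domain superpositions —
LNS6 against the β-neurexin LNS structure (1C4R) and LNS5 against the
laminin α2 LNS5 domain (1DYK).  Writes
results/reference_domain_geometry.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

import nrxgeom.neurexin as nrx
from nrxgeom.metal import analyze_metal_site
from nrxgeom.model import DomainDefinition, model_census, read_structure, select_domain
from nrxgeom.superpose import structure_align

ROOT = Path(__file__).resolve().parents[1]
REFERENCE = ROOT / "data" / "reference"
RESULTS = ROOT / "results"


def load(pdb_id):
    p = REFERENCE / f"{pdb_id}.pdb"
    return read_structure(p) if p.exists() else None


def main() -> int:
    m3asi = load("3asi")
    if m3asi is None:
        print(f"no deposited coordinates under {REFERENCE}; "
              "run analysis/01_fetch_reference.py first (requires network)")
        return 0
    out = {}
    chain = nrx.main_protein_chain(m3asi)
    c = model_census(m3asi)
    out["census"] = {"amino_acids": c.n_amino_acids, "waters": c.n_waters,
                     "ions": list(c.ion_identities), "sugars": c.n_sugars}
    print(f"3ASI census: {c.n_amino_acids} amino acids, {c.n_waters} waters, "
          f"{c.n_ions} ion(s) {c.ion_identities}, {c.n_sugars} sugar(s)")

    # the calcium of the LNS6 hyper-variable surface
    ca_ions = [(cid, r.auth_number) for cid, r in m3asi.residues() if r.category == "ion"
               and r.name.upper() == "CA"]
    for ion in ca_ions:
        rep = analyze_metal_site(m3asi, ion, cutoff=3.0)
        out["ca_site"] = {
            "ligands": [f"{l.residue_name}{l.auth_number}:{l.atom_name}({l.role}, "
                        f"{l.distance:.2f} Å)" for l in rep.ligands],
            "n_protein": rep.n_protein_ligands, "n_water": rep.n_water_ligands,
            "geometry": rep.geometry_class, "angular_rmsd_deg": rep.angular_rmsd,
        }
        print(f"Ca site {ion}: {rep.n_protein_ligands} protein + "
              f"{rep.n_water_ligands} water ligands, {rep.geometry_class} "
              f"(angular RMSD {rep.angular_rmsd:.1f}°)" if rep.angular_rmsd is not None
              else f"Ca site {ion}: {len(rep.ligands)} ligands, {rep.geometry_class}")

    for pdb_id, dom_range, label in (
        ("1c4r", nrx.LNS6_SHARED_RANGE, "LNS6 vs Nrx1β"),
        ("1dyk", nrx.LNS5_RANGE, "LNS5 vs laminin α2 LNS5"),
    ):
        other = load(pdb_id)
        if other is None:
            print(f"{pdb_id} not present; skipping {label}")
            continue
        sel = select_domain(m3asi, DomainDefinition("d", chain, *dom_range))
        ochain = nrx.main_protein_chain(other, min_residues=100)
        osel = select_domain(other, DomainDefinition("o", ochain, -10_000, 10_000))
        res = structure_align(sel, osel, seed="sequence")
        out[label] = {"rmsd_A": round(res.rmsd, 3),
                      "n_matched": res.correspondence.n_matched}
        print(f"{label}: RMSD {res.rmsd:.2f} Å over "
              f"{res.correspondence.n_matched} matched residues")

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "reference_domain_geometry.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
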