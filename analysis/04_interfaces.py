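#!/usr/bin/env python
"""Inter-domain buried surface area of the neurexin fragment.

On 3ASI: the two-sided buried ASA of the LNS5-EGF3 junction (with the
covalent Gly1045-Pro1046 linkage excluded) and of the EGF3-LNS6
junction, with per-residue contributions, plus the exposure of the
EGF3 signature tryptophan.  Writes results/reference_interfaces.json
and per-residue TSV tables.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import nrxgeom.neurexin as nrx
from nrxgeom.model import read_structure
from nrxgeom.sasa import buried_interface_area

ROOT = Path(__file__).resolve().parents[1]
REFERENCE = ROOT / "data" / "reference"
RESULTS = ROOT / "results"


def main() -> int:
    path = REFERENCE / "3asi.pdb"
    if not path.exists():
        print(f"no deposited coordinates under {REFERENCE}; "
              "run analysis/01_fetch_reference.py first (requires network)")
        return 0
    m = read_structure(path)
    chain = nrx.main_protein_chain(m)
    doms = nrx.alpha_domains(chain)
    RESULTS.mkdir(exist_ok=True)
    out = {}
    for name, (da, db, excl) in {
        "LNS5-EGF3": (doms["LNS5"], doms["EGF3"], list(nrx.LINKAGE_RESIDUES)),
        "EGF3-LNS6": (doms["EGF3"], doms["LNS6"], []),
    }.items():
        rep = buried_interface_area(m, da, db, exclude=excl)
        rows = [
            {"chain": cid, "residue": f"{num}{icode}", "buried_A2": round(area, 2)}
            for (cid, num, icode), area in sorted(rep.buried_per_residue.items())
            if area > 0.05
        ]
        pd.DataFrame(rows).to_csv(RESULTS / f"interface_{name}.tsv", sep="\t", index=False)
        out[name] = {"buried_total_A2": round(rep.buried_total, 1),
                     "excluded": rep.excluded_residues}
        print(f"{name}: {rep.buried_total:.1f} Å² buried"
              + (f" (excluding linkage {excl})" if excl else ""))
        top = max(rep.buried_per_residue, key=rep.buried_per_residue.get)
        print(f"  largest single contribution: residue {top[1]} "
              f"({rep.buried_per_residue[top]:.1f} Å²)")
    with open(RESULTS / "reference_interfaces.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
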