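from pathlib import Path

import numpy as np
import pytest

from nrxgeom.model import Atom, Residue, StructureModel

REFERENCE_DIR = Path(__file__).resolve().parents[1] / "data" / "reference"


def single_atom_model(coord=(0.0, 0.0, 0.0), element="C", name="CA", resname="GLY",
                      chain="A", number=1) -> StructureModel:
    return StructureModel(
        id="single",
        chains={chain: [Residue(number, resname,
                                [Atom(name, element, np.asarray(coord, float))])]},
    )


def load_reference(pdb_id: str):
    """Load a deposited coordinate set from data/reference, or fail the test.

    The deposited entries are not redistributed with the package; they
    are fetched by analysis/01_fetch_reference.py when network access
    is available.
    """
    from nrxgeom.model import read_structure

    for suffix in (".pdb", ".ent", ".cif"):
        path = REFERENCE_DIR / f"{pdb_id.lower()}{suffix}"
        if path.exists():
            return read_structure(path)
    pytest.fail(
        f"reference coordinate set {pdb_id} not found under {REFERENCE_DIR}; "
        "run `python analysis/01_fetch_reference.py` (requires network) to "
        "populate it",
        pytrace=False,
    )


@pytest.fixture
def carbon_pair():
    """Two isolated carbon atoms in separate chains, 100 Å apart."""
    a = Residue(1, "GLY", [Atom("CA", "C", np.zeros(3))])
    b = Residue(2, "GLY", [Atom("CA", "C", np.array([100.0, 0.0, 0.0]))])
    return StructureModel(id="pair", chains={"A": [a], "B": [b]})
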