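"""Structure model: I/O round trips, selection, sequence, census."""

import numpy as np
import pytest

from nrxgeom.errors import EmptySelectionError, FormatError, NrxGeomError, ParseError
from nrxgeom.model import (
    Atom,
    DomainDefinition,
    Residue,
    StructureModel,
    extract_sequence,
    model_census,
    read_structure,
    residue_category,
    select_domain,
    write_pdb,
)
from nrxgeom.simulate import make_two_domain_toy


def _mixed_model():
    """2 amino acids + 3 waters + 1 Ca ion + 1 NAG sugar."""
    chains = {
        "A": [
            Residue(10, "ALA", [Atom("CA", "C", [0, 0, 0]), Atom("CB", "C", [1.5, 0, 0])]),
            Residue(11, "MSE", [Atom("CA", "C", [3, 0, 0]), Atom("SE", "SE", [4, 1, 0])]),
        ],
        "W": [
            Residue(n, "HOH", [Atom("O", "O", [10.0 + n, 0, 0])], ) for n in (1, 2, 3)
        ],
        "I": [Residue(500, "CA", [Atom("CA", "CA", [20, 0, 0])])],
        "S": [Residue(600, "NAG", [Atom("C1", "C", [30, 0, 0])])],
    }
    return StructureModel(id="mixed", chains=chains)


class TestTypes:
    def test_atom_invariants(self):
        with pytest.raises(NrxGeomError):
            Atom("CA", "C", [np.nan, 0, 0])
        with pytest.raises(NrxGeomError):
            Atom("CA", "C", [0, 0, 0], occupancy=1.5)
        with pytest.raises(NrxGeomError):
            Atom("CA", "", [0, 0, 0])

    def test_duplicate_residue_rejected(self):
        r = Residue(1, "GLY", [Atom("CA", "C", [0, 0, 0])])
        with pytest.raises(NrxGeomError):
            StructureModel(id="dup", chains={"A": [r, Residue(1, "GLY", r.atoms)]})

    def test_domain_invariant(self):
        with pytest.raises(NrxGeomError):
            DomainDefinition("bad", "A", 10, 5)

    @pytest.mark.parametrize(
        "name,cat",
        [("ALA", "amino_acid"), ("MSE", "amino_acid"), ("HOH", "water"),
         ("CA", "ion"), ("NAG", "sugar"), ("XYZ", "other")],
    )
    def test_categories(self, name, cat):
        assert residue_category(name) == cat


class TestRoundTrip:
    def test_write_read_coordinates_stable(self, tmp_path):
        model, _ = make_two_domain_toy(seed=11, separation=9.0, n_per_domain=10)
        path = tmp_path / "toy.pdb"
        write_pdb(model, path)
        back = read_structure(path)
        assert np.abs(model.coords() - back.coords()).max() < 1e-3
        assert model_census(back) == model_census(model)

    def test_roundtrip_through_mmcif(self, tmp_path):
        import gemmi

        model = _mixed_model()
        pdb_path = tmp_path / "m.pdb"
        write_pdb(model, pdb_path)
        st = gemmi.read_pdb(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "m.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        back = read_structure(cif_path)  # auto-detected as mmCIF
        assert model_census(back) == model_census(model)
        assert np.abs(np.sort(model.coords(), axis=0) - np.sort(back.coords(), axis=0)).max() < 1e-3

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ParseError):
            read_structure(p)

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "x.pdb"
        write_pdb(single_chain_model(), p)
        with pytest.raises(FormatError):
            read_structure(p, format="dcd")

    def test_write_empty_model_rejected(self, tmp_path):
        with pytest.raises(NrxGeomError):
            write_pdb(StructureModel(id="e", chains={}), tmp_path / "e.pdb")

    def test_long_chain_id_rejected(self, tmp_path):
        m = StructureModel(
            id="lc", chains={"AB": [Residue(1, "GLY", [Atom("CA", "C", [0, 0, 0])])]}
        )
        with pytest.raises(NrxGeomError):
            write_pdb(m, tmp_path / "lc.pdb")


def single_chain_model(n=5, resname="ALA", start=1):
    residues = [
        Residue(start + i, resname, [Atom("CA", "C", [1.5 * i, 0.0, 0.0])])
        for i in range(n)
    ]
    return StructureModel(id="chain", chains={"A": residues})


class TestAltlocPolicy:
    PDB_TEXT = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C\n"
        "ATOM      3  CA AALA A   2       9.000   0.000   0.000  0.50 10.00           C\n"
        "ATOM      4  CA BALA A   2      12.000   0.000   0.000  0.50 10.00           C\n"
        "END\n"
    )

    def test_highest_occupancy_kept_ties_alphabetical(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(self.PDB_TEXT)
        m = read_structure(p)
        res1 = m.find_residue("A", 1)
        res2 = m.find_residue("A", 2)
        assert len(res1.atoms) == 1 and res1.atoms[0].coord[0] == pytest.approx(5.0)
        # tie at 0.5/0.5 -> altloc A wins
        assert len(res2.atoms) == 1 and res2.atoms[0].coord[0] == pytest.approx(9.0)

    def test_hydrogens_dropped(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "ATOM      2  HA  ALA A   1       1.000   0.000   0.000  1.00 10.00           H\n"
            "END\n"
        )
        p = tmp_path / "h.pdb"
        p.write_text(text)
        m = read_structure(p)
        assert [a.name for a in m.find_residue("A", 1).atoms] == ["CA"]


class TestSelection:
    def test_range_selection_counts(self):
        m = single_chain_model(n=20, start=100)
        sub = select_domain(m, DomainDefinition("d", "A", 105, 110))
        assert sub.n_residues() == 6

    def test_waters_excluded_by_default(self):
        m = _mixed_model()
        with pytest.raises(EmptySelectionError):
            select_domain(m, DomainDefinition("w", "W", 1, 3))
        sub = select_domain(m, DomainDefinition("w", "W", 1, 3), categories=("water",))
        assert sub.n_residues() == 3

    def test_out_of_range_is_empty_selection(self):
        m = single_chain_model(n=5, start=867)
        with pytest.raises(EmptySelectionError):
            select_domain(m, DomainDefinition("d", "A", 1, 5))

    def test_disjoint_union_census_adds(self):
        m = single_chain_model(n=30, start=1)
        d1 = DomainDefinition("a", "A", 1, 10)
        d2 = DomainDefinition("b", "A", 11, 30)
        c1 = model_census(select_domain(m, d1))
        c2 = model_census(select_domain(m, d2))
        whole = model_census(select_domain(m, DomainDefinition("ab", "A", 1, 30)))
        assert c1.n_amino_acids + c2.n_amino_acids == whole.n_amino_acids == 30


class TestSequence:
    def test_penta_alanine(self):
        m = single_chain_model(n=5)
        pairs = extract_sequence(m, DomainDefinition("d", "A", 1, 5))
        assert pairs == [(1, "A"), (2, "A"), (3, "A"), (4, "A"), (5, "A")]

    def test_mse_maps_to_x(self):
        m = _mixed_model()
        pairs = extract_sequence(m, DomainDefinition("d", "A", 10, 11))
        assert pairs == [(10, "A"), (11, "X")]

    def test_no_amino_acids_errors(self):
        m = _mixed_model()
        with pytest.raises(EmptySelectionError):
            extract_sequence(m, DomainDefinition("d", "W", 1, 3))


class TestCensus:
    def test_mixed_model_counts(self):
        c = model_census(_mixed_model())
        assert (c.n_amino_acids, c.n_waters, c.n_ions, c.n_sugars) == (2, 3, 1, 1)
        assert c.ion_identities == ("CA",)

    def test_empty_model_all_zero(self):
        c = model_census(StructureModel(id="e", chains={}))
        assert (c.n_amino_acids, c.n_waters, c.n_ions, c.n_sugars) == (0, 0, 0, 0)

    def test_permutation_invariant(self):
        m = _mixed_model()
        shuffled = StructureModel(
            id="shuf",
            chains={cid: list(reversed(res)) for cid, res in m.chains.items()},
        )
        assert model_census(shuffled) == model_census(m)
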