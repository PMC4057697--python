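"""PDB round-trips, ligand extraction and distance-based bond perception."""

from __future__ import annotations

import numpy as np
import pytest

from ppargpharm import structure_io as sio, synthetic_data as sd
from ppargpharm.model import Atom, LigandInstance, ModelError
from ppargpharm.structure_io import LigandNotFoundError, PdbParseError


def test_empty_text_gives_empty_model():
    model = sio.read_pdb("HEADER    EMPTY\nEND\n")
    assert model.chains == [] and model.het_groups == [] and model.waters == []


def test_helix_fixture_roundtrip_preserves_identities_and_coordinates():
    model = sd.make_helix(3 + 1, "AASA")
    text = sio.write_pdb(model)
    back = sio.read_pdb(text)
    assert len(back.chains) == 1
    orig = model.chains[0].residues
    re_read = back.chains[0].residues
    assert [(r.name, r.number) for r in re_read] == \
        [(r.name, r.number) for r in orig]
    for r1, r2 in zip(orig, re_read):
        for a1, a2 in zip(r1.atoms, r2.atoms):
            assert a1.name == a2.name
            assert np.allclose(a1.pos, a2.pos, atol=1e-3)


def test_roundtrip_of_transformed_model_matches_in_memory_transform():
    model = sd.make_helix(6)
    moved, manifest = sd.perturb(model, "rigid", seed=5)
    back = sio.read_pdb(sio.write_pdb(moved))
    got = np.array([a.pos for a in back.all_atoms()])
    want = np.array([a.pos for a in moved.all_atoms()])
    assert np.allclose(got, want, atol=1e-3)


def test_malformed_coordinate_line_names_line_number():
    bad = "ATOM      1  CA  ALA A   1      xx.xxx   0.000   0.000  1.00  0.00           C"
    with pytest.raises(PdbParseError, match="line 1"):
        sio.read_pdb(bad)


def test_atom_name_longer_than_four_chars_rejected_on_write():
    model = sd.make_helix(4)
    model.chains[0].residues[0].atoms[0].name = "TOOLONG"
    with pytest.raises(ModelError, match="longer than 4"):
        sio.write_pdb(model)


def test_altloc_resolution_keeps_highest_occupancy():
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C\n"
        "END\n")
    model = sio.read_pdb(text)
    ca = model.chains[0].residues[0].atom("CA")
    assert ca.pos[0] == pytest.approx(1.0)


class TestExtractLigand:
    def test_missing_component_raises_not_found(self, toy_complex):
        model, _ = toy_complex
        with pytest.raises(LigandNotFoundError):
            sio.extract_ligand(model, "BRL")

    def test_single_copy_extracted(self, toy_complex):
        model, _ = toy_complex
        lig = sio.extract_ligand(model, "LIG")
        assert lig.comp_id == "LIG" and lig.heavy_atoms

    def test_dual_copies_need_chain_disambiguation(self, toy_complex):
        model, _ = toy_complex
        model = model.copy()
        twin = model.het_groups[0].copy()
        twin.chain_id = "M"
        model.het_groups.append(twin)
        with pytest.raises(ModelError, match="ambiguous"):
            sio.extract_ligand(model, "LIG")
        assert sio.extract_ligand(model, "LIG", "M").chain_id == "M"


class TestBondPerception:
    def test_two_carbons_at_bonding_distance(self):
        lig = LigandInstance("ETH", "L", 1, [
            Atom("C1", "C", np.zeros(3)), Atom("C2", "C", np.array([1.5, 0, 0]))])
        out = sio.perceive_ligand_bonds(lig)
        assert [(b[0], b[1], b[2]) for b in out.bonds] == [(0, 1, 1)]

    def test_idealized_benzene_is_one_aromatic_six_ring(self):
        pts = []
        for k in range(6):
            t = np.radians(60 * k)
            pts.append(Atom(f"C{k+1}", "C",
                            1.395 * np.array([np.cos(t), np.sin(t), 0.0])))
        out = sio.perceive_ligand_bonds(LigandInstance("BNZ", "L", 1, pts))
        assert len(out.bonds) == 6
        assert all(b[3] for b in out.bonds)

    def test_cyclohexane_chair_not_aromatic(self):
        # puckered ring: alternating z displacement breaks planarity
        pts = []
        for k in range(6):
            t = np.radians(60 * k)
            pts.append(Atom(f"C{k+1}", "C", np.array(
                [1.46 * np.cos(t), 1.46 * np.sin(t), 0.25 * (-1) ** k])))
        out = sio.perceive_ligand_bonds(LigandInstance("CHX", "L", 1, pts))
        assert not any(b[3] for b in out.bonds)

    def test_tzd_head_ring_and_carbonyls(self, annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["tzd_head"])
        out = sio.perceive_ligand_bonds(
            LigandInstance("TZD", "L", 1, [a.copy() for a in lig.atoms]))
        elements_in_ring = sorted(
            out.atoms[i].element for i in range(5))  # S1 C2 N3 C4 C5
        assert elements_in_ring == ["C", "C", "C", "N", "S"]
        carbonyls = [b for b in out.bonds if b[2] == 2]
        assert len(carbonyls) == 2
        assert not any(b[3] for b in out.bonds)  # saturated ring

    @pytest.mark.parametrize("aa", list("ACDEFGHIKLMNPQRSTVWY"))
    def test_amino_acid_geometries_reproduce_reference_bond_graph(self, aa):
        """Distance perception on embedded 3D amino acids must recover the
        chemical bond graph exactly (independent oracle: RDKit topology)."""
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSequence(aa))
        params = AllChem.ETKDGv3()
        params.randomSeed = 7
        assert AllChem.EmbedMolecule(mol, params) == 0
        AllChem.MMFFOptimizeMolecule(mol)
        conf = mol.GetConformer()
        atoms = [Atom(f"A{i}", a.GetSymbol(),
                      np.array(list(conf.GetAtomPosition(i))))
                 for i, a in enumerate(mol.GetAtoms())]
        out = sio.perceive_ligand_bonds(LigandInstance(aa, "L", 1, atoms))
        ref = {frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
               for b in mol.GetBonds()}
        got = {frozenset((i, j)) for i, j, _o, _a in out.bonds}
        assert got == ref


class TestFetch:
    def test_invalid_accession_rejected(self, tmp_path):
        with pytest.raises(sio.FetchError):
            sio.fetch_structure("XXXXX", cache_dir=tmp_path)

    def test_cached_entry_served_without_network(self, tmp_path, toy_complex):
        model, _ = toy_complex
        (tmp_path / "1TOY.pdb").write_text(sio.write_pdb(model))
        got = sio.fetch_structure("1TOY", cache_dir=tmp_path)
        assert got.n_atoms == model.n_atoms

    def test_ligand_serials_subset_of_model(self, toy_complex):
        model, _ = toy_complex
        text = sio.write_pdb(model)
        back = sio.read_pdb(text)
        all_serials = {a.serial for a in back.all_atoms()}
        lig = sio.extract_ligand(back, "LIG")
        assert {a.serial for a in lig.atoms} <= all_serials
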