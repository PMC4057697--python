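"""Ionisation rules, histidine tautomers and polar-hydrogen placement."""

from __future__ import annotations

import numpy as np
import pytest

from ppargpharm import protonation as pr, synthetic_data as sd
from ppargpharm.geometry import place_atom
from ppargpharm.model import Atom, Residue


def test_poly_gly_has_no_charged_residues():
    model = sd.make_helix(6, "GGGGGG")
    assignment = pr.assign_ionization(model)
    assert assignment.net_charge == 0
    assert not assignment.residue_charges


def test_asp_deprotonated_lys_arg_protonated():
    model = sd.make_helix(5, ["ALA", "ASP", "LYS", "ARG", "GLU"])
    a = pr.assign_ionization(model)
    states = {r.number: a.state_of(r) for r in model.iter_protein_residues()}
    assert states[2] == "deprotonated-acid"
    assert states[3] == "protonated-base"
    assert states[4] == "protonated-base"
    assert a.net_charge == -1 + 1 + 1 - 1


def test_other_ph_refused():
    with pytest.raises(NotImplementedError):
        pr.assign_ionization(sd.make_helix(4), ph=5.0)


def _lone_his_with_probe(n_name: str):
    """A single histidine plus a carbonyl O parked 2.9 A along the
    direction the ring N-H would point; both tautomers enumerated by the
    assigner, the probe decides."""
    from ppargpharm.geometry import unit
    from ppargpharm.model import Chain, StructureModel

    helix = sd.make_helix(5, ["GLY", "GLY", "HIS", "GLY", "GLY"])
    his = helix.chains[0].residue(3).copy()
    ring = {nm: his.atom(nm) for nm in ("CG", "ND1", "CE1", "NE2", "CD2")}
    n = ring[n_name]
    nbrs = {"ND1": ("CG", "CE1"), "NE2": ("CE1", "CD2")}[n_name]
    direction = -unit(unit(ring[nbrs[0]].pos - n.pos)
                      + unit(ring[nbrs[1]].pos - n.pos))
    probe = Residue("ALA", 50, "", "A",
                    [Atom("O", "O", n.pos + 2.9 * direction)])
    model = StructureModel("HIS", [Chain("A", [his, probe])])
    return model, his


def test_his_tautomer_follows_nearby_acceptor():
    # enumerate both tautomers: an acceptor reachable only from N-delta
    # selects the N-delta-H tautomer, and vice versa
    model, his = _lone_his_with_probe("ND1")
    assert pr.assign_ionization(model).state_of(his) == "HIS-Nd"
    model, his = _lone_his_with_probe("NE2")
    assert pr.assign_ionization(model).state_of(his) == "HIS-Ne"


def test_his_defaults_to_epsilon_tautomer_when_isolated():
    model = sd.make_helix(5, ["GLY", "GLY", "HIS", "GLY", "GLY"])
    a = pr.assign_ionization(model)
    assert a.state_of(model.chains[0].residue(3)) == "HIS-Ne"


class TestHydrogenPlacement:
    def test_backbone_carbonyl_gets_no_hydrogen(self):
        model = sd.make_helix(5)
        out = pr.place_polar_hydrogens(model, pr.assign_ionization(model))
        for res in out.iter_protein_residues():
            o = res.atom("O")
            for a in res.atoms:
                if a.is_hydrogen:
                    assert np.linalg.norm(a.pos - o.pos) > 1.2

    def test_lys_nz_gets_exactly_three_hydrogens(self):
        model = sd.make_helix(5, ["GLY", "GLY", "LYS", "GLY", "GLY"])
        out = pr.place_polar_hydrogens(model, pr.assign_ionization(model))
        lys = out.chains[0].residue(3)
        nz = lys.atom("NZ")
        hs = [a for a in lys.atoms if a.is_hydrogen
              and np.linalg.norm(a.pos - nz.pos) <= 1.2]
        assert len(hs) == 3

    def test_ser_rotamer_chosen_by_exhaustive_three_rotamer_oracle(self):
        model = sd.make_helix(5, ["GLY", "GLY", "SER", "GLY", "GLY"])
        ser = model.chains[0].residue(3)
        og, cb, ca = ser.atom("OG"), ser.atom("CB"), ser.atom("CA")
        # park an acceptor straight along the +60 rotamer direction
        h60 = place_atom(ca.pos, cb.pos, og.pos, 0.96, 109.5, 60.0)
        acceptor_pos = og.pos + 2.9 * (h60 - og.pos) / np.linalg.norm(h60 - og.pos)
        model.chains[0].residues.append(
            Residue("ALA", 50, "", "A", [Atom("O", "O", acceptor_pos)]))
        out = pr.place_polar_hydrogens(model, pr.assign_ionization(model))
        hg = out.chains[0].residue(3).atom("HG")
        # oracle: of the three staggered rotamers, +60 is the only one that
        # hydrogen-bonds the acceptor, so the placed H must sit there
        assert np.linalg.norm(hg.pos - h60) < 1e-6

    def test_idempotent_and_h_attached_to_exactly_one_heavy_atom(self, toy_complex):
        model, _ = toy_complex
        a = pr.assign_ionization(model)
        once = pr.place_polar_hydrogens(model, a)
        twice = pr.place_polar_hydrogens(once, a)
        assert once.n_atoms == twice.n_atoms
        p1 = np.array([x.pos for x in once.all_atoms()])
        p2 = np.array([x.pos for x in twice.all_atoms()])
        assert np.allclose(p1, p2)
        heavy = np.array([x.pos for x in once.all_atoms() if not x.is_hydrogen])
        for atom in once.all_atoms():
            if atom.is_hydrogen and atom.placed:
                d = np.linalg.norm(heavy - atom.pos, axis=1)
                assert (d <= 1.4).sum() == 1


class TestLigandRules:
    def test_carboxylate_minus_one(self, annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["carboxylate", "alkyl"])
        assert pr._ligand_rule_charge(lig) == -1

    def test_aliphatic_amine_protonated(self, annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["amine"])
        assert pr._ligand_rule_charge(lig) == +1

    def test_tzd_ring_nitrogen_neutral(self, annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["tzd_head"])
        assert pr._ligand_rule_charge(lig) == 0

    def test_override_wins(self, toy_complex):
        model, _ = toy_complex
        a = pr.assign_ionization(model, ligand_overrides={"LIG": -2})
        assert list(a.ligand_charges.values()) == [-2]
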