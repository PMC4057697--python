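"""Hydrogen bonds, salt/water bridges and activation-helix contacts."""

from __future__ import annotations

import numpy as np
import pytest

from ppargpharm import interactions as ia, protonation as pr, synthetic_data as sd
from ppargpharm.model import Atom, Chain, LigandInstance, ModelError, Residue, StructureModel


def _one_residue_model(res: Residue) -> StructureModel:
    return StructureModel("MIN", [Chain(res.chain_id, [res])])


def test_alkane_ligand_yields_no_hbonds(toy_protonated):
    model, _ = toy_protonated
    alkane, _m = sd.make_annotated_ligand(["alkyl"])
    assert ia.find_hbonds(model, alkane) == []


def test_planted_linear_hydroxyl_to_carbonyl_hbond():
    # O-H ... O=C at 2.8 A and 180 degrees, built atom by atom
    don = LigandInstance("LIG", "L", 900, [
        Atom("O1", "O", np.zeros(3)),
        Atom("HO1", "H", np.array([0.96, 0.0, 0.0])),
        Atom("C9", "C", np.array([-1.43, 0.0, 0.0]))],
        bonds=[(0, 1, 1, False), (0, 2, 1, False)])
    acc = Residue("ALA", 10, "", "A", [
        Atom("O", "O", np.array([2.8, 0.0, 0.0])),
        Atom("C", "C", np.array([4.03, 0.0, 0.0]))])
    hbs = ia.find_hbonds(_one_residue_model(acc), don)
    assert len(hbs) == 1
    hb = hbs[0]
    assert hb.direction == "ligand->protein"
    assert hb.distance == pytest.approx(2.8)
    assert hb.angle == pytest.approx(180.0)


def test_planted_hbonds_recovered_exactly(toy_protonated):
    model, manifest = toy_protonated
    lig = model.het_groups[0]
    hbs = ia.find_hbonds(model, lig)
    got = sorted((hb.protein_residue,
                  (hb.donor if not hb.donor.is_ligand else hb.acceptor).atom_name)
                 for hb in hbs)
    want = sorted(((h["resname"], h["resnum"]), h["protein_atom"])
                  for h in manifest.hbonds)
    assert got == want


def test_criteria_monotonicity(toy_protonated):
    model, _ = toy_protonated
    lig = model.het_groups[0]
    strict = {(str(h.donor), str(h.acceptor))
              for h in ia.find_hbonds(model, lig, ia.HBCriteria(3.2, 130.0))}
    loose = {(str(h.donor), str(h.acceptor))
             for h in ia.find_hbonds(model, lig, ia.HBCriteria(3.5, 120.0))}
    assert strict <= loose


class TestSaltBridges:
    def _model_with_arg(self, gap: float):
        lig, _ = sd.make_annotated_ligand(["carboxylate"])
        o2 = lig.atom("O2")
        arg = Residue("ARG", 20, "", "A", [
            Atom("NH1", "N", o2.pos + np.array([0.0, -gap, 0.0])),
            Atom("CZ", "C", o2.pos + np.array([0.0, -gap - 1.33, 0.0]))])
        return _one_residue_model(arg), lig

    def test_neutral_ligand_gives_nothing(self, toy_protonated):
        model, _ = toy_protonated
        phenyl, _m = sd.make_annotated_ligand(["phenyl"])
        assert ia.find_salt_bridges(model, phenyl) == []

    def test_carboxylate_near_guanidinium_detected(self):
        model, lig = self._model_with_arg(3.5)
        records = ia.find_salt_bridges(model, lig)
        assert len(records) == 1
        assert records[0].residue_a == ("ARG", 20)
        assert records[0].distance == pytest.approx(3.5)

    def test_same_pair_beyond_cutoff_empty(self):
        model, lig = self._model_with_arg(4.5)
        assert ia.find_salt_bridges(model, lig) == []


class TestWaterBridges:
    def test_no_waters_no_bridges(self):
        lig, _ = sd.make_annotated_ligand(["hydroxyl"])
        model = StructureModel("DRY", [Chain("A", [])])
        assert ia.find_water_bridges(model, lig) == []

    def test_planted_triad_recovered_exactly(self, toy_protonated):
        model, manifest = toy_protonated
        lig = model.het_groups[0]
        got = sorted((a.atom_name, w.resnum, p.residue_key)
                     for a, w, p in ia.find_water_bridges(model, lig))
        want = sorted((d["ligand_atom"], d["water_number"],
                       (d["resname"], d["resnum"]))
                      for d in manifest.water_bridges)
        assert got == want

    def test_overlong_protein_leg_breaks_bridge(self):
        lig, _ = sd.make_annotated_ligand(["hydroxyl"])
        o1 = lig.atom("O1")
        water = Residue("HOH", 5001, "", "W",
                        [Atom("O", "O", o1.pos + np.array([0.0, 2.8, 0.0]))])
        ser = Residue("SER", 30, "", "A", [
            Atom("OG", "O", o1.pos + np.array([0.0, 2.8 + 4.0, 0.0]))])
        model = StructureModel("WB", [Chain("A", [ser])], waters=[water])
        assert ia.find_water_bridges(model, lig) == []


def _focus_contact_model() -> StructureModel:
    """Tyr472 (activation-helix focus) donating to Glu322 outside it."""
    oh = np.zeros(3)
    tyr = Residue("TYR", 472, "", "A", [
        Atom("OH", "O", oh),
        Atom("HH", "H", oh + np.array([0.96, 0.0, 0.0])),
        Atom("CZ", "C", oh + np.array([-1.38, 0.0, 0.0]))])
    glu = Residue("GLU", 322, "", "A", [
        Atom("OE1", "O", oh + np.array([2.8, 0.0, 0.0])),
        Atom("CD", "C", oh + np.array([4.05, 0.0, 0.0]))])
    return StructureModel("FC", [Chain("A", [tyr, glu])])


class TestHelixContacts:
    ANNOTATION = ia.default_helix_annotation()

    def test_empty_focus_region_raises(self):
        model = sd.make_helix(6)  # residues 1..6, far below the LBD span
        with pytest.raises(ModelError, match="focus"):
            ia.helix_contacts(model, self.ANNOTATION)

    def test_planted_cross_helix_pair_labelled(self):
        records = ia.helix_contacts(_focus_contact_model(), self.ANNOTATION)
        assert len(records) == 1
        rec = records[0]
        assert rec.residue_a == ("TYR", 472) and rec.residue_b == ("GLU", 322)
        assert rec.helix_a == "H12" and rec.helix_b == "H5"

    def test_apo_without_polar_contacts_is_empty(self):
        model = _focus_contact_model()
        # pull the acceptor out of range
        model.chains[0].residue(322).atom("OE1").pos += np.array([5.0, 0, 0])
        model.chains[0].residue(322).atom("CD").pos += np.array([5.0, 0, 0])
        assert ia.helix_contacts(model, self.ANNOTATION) == []


class TestUniqueContacts:
    R1 = ia.ContactRecord(("TYR", 472), ("GLU", 322), "H12", "H5", "hbond")
    R2 = ia.ContactRecord(("LYS", 474), ("LYS", 319), "after H12", "H4", "hbond")

    def test_identical_sets_cancel(self):
        assert ia.unique_contacts([self.R1, self.R2], [self.R2, self.R1]) == []

    def test_difference_of_planted_sets(self):
        assert ia.unique_contacts([self.R1, self.R2], [self.R2]) == [self.R1]

    def test_empty_apo_returns_everything(self):
        assert ia.unique_contacts([self.R1], []) == [self.R1]


class TestHelixAnnotation:
    def test_shipped_annotation_anchors(self):
        ann = ia.default_helix_annotation()
        assert ann.label(289) == "H3"
        assert ann.label(323) == "H5"
        assert ann.label(449) == "H11"
        assert ann.label(473) == "H12"
        assert ann.label(474) == "after H12"
        assert ann.label(477) == "after H12"
        assert ann.label(466) == "H10/11-H12 linker"

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ModelError, match="overlap"):
            ia.HelixAnnotation({"H1": (1, 10), "H2": (5, 20)}, vicinity=(30, 40))

    def test_computed_annotation_finds_synthetic_helix(self):
        model = sd.make_helix(18)
        ann = ia.compute_helix_annotation(model)
        assert len(ann.ranges) == 1
        lo, hi = next(iter(ann.ranges.values()))
        assert hi - lo + 1 >= 10  # most of an 18-residue ideal helix
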