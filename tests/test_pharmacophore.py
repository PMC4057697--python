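"""Annotation points, query building, static matching and classification."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from ppargpharm import pharmacophore as ph, synthetic_data as sd
from ppargpharm.geometry import rotation_about_axis
from ppargpharm.model import ModelError
from ppargpharm.pharmacophore import FrameMismatchError, MissingHydrogensError
from ppargpharm.superposition import RigidTransform


@pytest.mark.parametrize("fragments", [
    ["methane"], ["phenyl"], ["carboxylate", "phenyl"], ["hydroxyl"],
    ["amide"], ["amine"], ["tzd_head"], ["tzd_head", "phenyl", "alkyl"],
])
def test_annotation_counts_match_fixture_manifest(fragments,
                                                  annotated_ligand_factory):
    lig, manifest = annotated_ligand_factory(fragments)
    got = Counter(p.kind for p in ph.annotate(lig))
    for kind, n in manifest.annotation_counts.items():
        assert got.get(kind, 0) == n, f"{kind} count off for {fragments}"


def test_methane_is_one_hydrophobic_atom_and_cluster(annotated_ligand_factory):
    lig, _ = annotated_ligand_factory(["methane"])
    got = Counter(p.kind for p in ph.annotate(lig))
    assert got["HydA"] == 1 and got["Hyd"] == 1
    assert got["Don"] == got["Acc"] == 0


def test_benzene_single_aromatic_centroid_at_ring_centre(annotated_ligand_factory):
    lig, _ = annotated_ligand_factory(["phenyl"])
    aro = [p for p in ph.annotate(lig) if p.kind == "Aro"]
    assert len(aro) == 1
    ring = np.array([a.pos for a in lig.atoms if a.element == "C"])
    assert np.allclose(aro[0].position, ring.mean(axis=0), atol=1e-9)


def test_acetate_anion_group_centroid_and_two_acceptors(annotated_ligand_factory):
    lig, _ = annotated_ligand_factory(["carboxylate"])
    pts = ph.annotate(lig)
    ani = [p for p in pts if p.kind == "Ani"]
    assert len(ani) == 1
    oxygens = np.array([lig.atom("O1").pos, lig.atom("O2").pos])
    assert np.allclose(ani[0].position, oxygens.mean(axis=0), atol=1e-9)
    assert sum(p.kind == "Acc" for p in pts) == 2


def test_missing_hydrogens_instruct_to_protonate(annotated_ligand_factory):
    lig, _ = annotated_ligand_factory(["amide"])
    keep = [i for i, a in enumerate(lig.atoms) if not a.is_hydrogen]
    remap = {o: n for n, o in enumerate(keep)}
    lig.bonds = [(remap[i], remap[j], o, ar) for i, j, o, ar in lig.bonds
                 if i in remap and j in remap]
    lig.atoms = [lig.atoms[i] for i in keep]
    with pytest.raises(MissingHydrogensError, match="protonation"):
        ph.annotate(lig)


class TestBuildQuery:
    SPEC1 = [{"id": "F1", "kinds": ["Don", "Acc"], "arm": "I"}]

    def test_single_ligand_feature_on_qualifying_point(self,
                                                       annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["hydroxyl"])
        pts = ph.annotate(lig)
        q = ph.build_query([("L1", pts)], feature_spec=self.SPEC1)
        don = [p for p in pts if p.kind in ("Don", "Acc")]
        dists = [np.linalg.norm(q.features[0].centroid - p.position)
                 for p in don]
        assert min(dists) < 1e-9

    def test_three_identical_actives_degenerate_to_single_case(self,
                                                               annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["hydroxyl"])
        pts = ph.annotate(lig)
        q1 = ph.build_query([("L1", pts)], feature_spec=self.SPEC1)
        q3 = ph.build_query([("A", pts), ("B", pts), ("C", pts)],
                            feature_spec=self.SPEC1)
        assert np.allclose(q1.features[0].centroid, q3.features[0].centroid)

    def test_unsupported_mandatory_feature_named_in_error(self,
                                                          annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["alkyl"])  # nothing polar
        pts = ph.annotate(lig)
        with pytest.raises(ModelError, match="F1"):
            ph.build_query([("L1", pts)], feature_spec=self.SPEC1)

    def test_query_json_roundtrip_is_stable(self, annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["tzd_head", "phenyl"])
        pts = ph.annotate(lig)
        spec = [{"id": "F1", "kinds": ["Don", "Acc"], "arm": "I"},
                {"id": "F3", "kinds": ["Hyd", "Aro"], "arm": "I"}]
        q = ph.build_query([("L1", pts)], feature_spec=spec)
        text = q.to_json()
        assert ph.PharmacophoreQuery.from_json(text).to_json() == text


def _seven_feature_setup(factory):
    anchors = [np.array([0.0, 0, 0]), np.array([0.0, 5, 0]),
               np.array([5.0, 0, 0]), np.array([0.0, 0, 6]),
               np.array([5.0, 5, 0]), np.array([0.0, 5, 6]),
               np.array([5.0, 0, 6])]
    frags = ["tzd_head", "carboxylate", "phenyl", "hydroxyl", "alkyl",
             "amide", "phenyl"]
    lig, _ = factory(frags, anchors=anchors)
    pts = ph.annotate(lig)
    spec = []
    kinds_cycle = [("Don", "Acc"), ("Acc",), ("Hyd", "Aro"), ("Don", "Acc"),
                   ("Hyd", "Aro"), ("Don", "Acc"), ("Hyd", "Aro")]
    arms = ["I", "I", "I", "II", "II", "I", "I"]
    for i, (kinds, arm) in enumerate(zip(kinds_cycle, arms), start=1):
        spec.append({"id": f"F{i}", "kinds": list(kinds), "arm": arm})
    query = ph.build_query([("ACT", pts)], feature_spec=spec)
    return query, lig, pts


class TestMatch:
    def test_zero_annotation_points_all_minus(self, annotated_ligand_factory):
        query, _lig, _pts = _seven_feature_setup(annotated_ligand_factory)
        vec = ph.match(query, [], "EMPTY")
        assert vec.values == (False,) * 7

    def test_active_self_matches_everywhere(self, annotated_ligand_factory):
        query, _lig, pts = _seven_feature_setup(annotated_ligand_factory)
        assert ph.match(query, pts, "ACT").values == (True,) * 7

    def test_hydrophobic_decoy_matches_only_hydrophobic_features(
            self, annotated_ligand_factory):
        query, _lig, _pts = _seven_feature_setup(annotated_ligand_factory)
        anchors = [query.feature("F3").centroid, query.feature("F5").centroid,
                   query.feature("F7").centroid]
        decoy, _m = annotated_ligand_factory(
            ["methane", "methane", "methane"], anchors=anchors)
        vec = ph.match(query, ph.annotate(decoy), "DCY")
        assert vec.values == (False, False, True, False, True, False, True)
        ok, why = ph.classify_full_agonist(vec)
        assert not ok and "F1 or F2" in why

    def test_radius_growth_never_turns_plus_into_minus(
            self, annotated_ligand_factory):
        query, _lig, pts = _seven_feature_setup(annotated_ligand_factory)
        base = ph.match(query, pts, "ACT").values
        for f in query.features:
            f.radius = f.radius * 3
        grown = ph.match(query, pts, "ACT").values
        assert all(b <= g for b, g in zip(base, grown))

    def test_rigid_motion_equivariance(self, annotated_ligand_factory):
        query, lig, pts = _seven_feature_setup(annotated_ligand_factory)
        rng = np.random.default_rng(21)
        for _trial in range(5):
            rot = rotation_about_axis(rng.normal(size=3),
                                      float(rng.uniform(0, 360)))
            t = rng.uniform(-8, 8, size=3)
            transform = RigidTransform(rot, t)
            moved_q = ph.PharmacophoreQuery(
                [ph.PharmacophoreFeature(
                    f.id, f.kinds, transform.apply(f.centroid[None])[0],
                    f.radius, f.arm) for f in query.features])
            moved_pts = [ph.AnnotationPoint(
                p.kind, transform.apply(p.position[None])[0], p.parents)
                for p in pts]
            assert ph.match(moved_q, moved_pts, "ACT").values == \
                ph.match(query, pts, "ACT").values

    def test_untransformed_ligand_frame_mismatch(self, annotated_ligand_factory):
        query, _lig, pts = _seven_feature_setup(annotated_ligand_factory)
        far = [ph.AnnotationPoint(p.kind, p.position + 200.0, p.parents)
               for p in pts]
        with pytest.raises(FrameMismatchError):
            ph.match(query, far, "FAR")


class TestClassification:
    def test_agrees_with_truth_table_over_all_128_vectors(self):
        for bits in itertools.product([False, True], repeat=7):
            f1, f2, f3, f4, f5, f6, f7 = bits
            expected = (f1 or f2) and f3 and (f4 or f5 or f6 or f7)
            got, _why = ph.classify_full_agonist(bits)
            assert got == expected

    def test_explanation_lists_failed_clauses(self):
        ok, why = ph.classify_full_agonist(
            [False, False, True, True, True, True, True])
        assert not ok and "F1 or F2" in why
        ok, why = ph.classify_full_agonist(
            [True, True, False, False, False, False, False])
        assert not ok and "F3" in why and "F4-F7" in why

    def test_wrong_length_rejected(self):
        with pytest.raises(ModelError):
            ph.classify_full_agonist([True] * 6)


class TestScreen:
    def test_empty_set_empty_matrix(self, annotated_ligand_factory):
        query, _lig, _pts = _seven_feature_setup(annotated_ligand_factory)
        assert ph.screen(query, []).empty

    def test_matrix_shape_and_ec50_ordering(self, annotated_ligand_factory):
        import pandas as pd

        query, _lig, pts = _seven_feature_setup(annotated_ligand_factory)
        ec50 = pd.DataFrame({"ligand": ["B", "A"], "ec50_low_nM": [5.0, 1.0]})
        table = ph.screen(query, [("A", pts), ("B", pts)], ec50=ec50)
        assert list(table["ligand"]) == ["A", "B"]
        assert set("F1 F2 F3 F4 F5 F6 F7".split()) <= set(table.columns)
        assert table["full_agonist"].all()
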