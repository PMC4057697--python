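"""Kabsch superposition, RMSD selections, overlays and ligand relaxation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ppargpharm import structure_io as sio, superposition as sp, synthetic_data as sd
from ppargpharm.geometry import dihedral_deg, rotation_about_axis
from ppargpharm.model import Atom, LigandInstance, ModelError


def _random_points(rng, n):
    return rng.normal(scale=3.0, size=(n, 3))


class TestKabsch:
    def test_identical_sets_identity_rotation(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        res = sp.kabsch(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.transform.rotation, np.eye(3))

    def test_rigid_motion_recovered_to_zero_rmsd(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 1.5, 0], [1, 1, 2.0]])
        rot = rotation_about_axis([0, 0, 1.0], 90.0)
        moved = pts @ rot.T + np.array([5.0, 0, 0])
        res = sp.kabsch(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_and_degenerate_raise(self):
        with pytest.raises(ModelError, match="mismatch"):
            sp.kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(4.0), np.array([1.0, 0, 0]))
        with pytest.raises(ModelError, match="collinear|degenerate"):
            sp.kabsch(line, line)

    def test_rmsd_symmetric_and_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(11)
        a = _random_points(rng, 7)
        b = a + rng.normal(scale=0.3, size=a.shape)
        r1 = sp.kabsch(a, b).rmsd
        r2 = sp.kabsch(b, a).rmsd
        assert r1 == pytest.approx(r2, abs=1e-9)
        rot = rotation_about_axis(rng.normal(size=3), 63.0)
        b_moved = b @ rot.T + np.array([4.0, -2.0, 9.0])
        assert sp.kabsch(a, b_moved).rmsd == pytest.approx(r1, abs=1e-9)

    def test_agrees_with_independent_quaternion_solver(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        for n in (4, 6, 9):
            a = _random_points(rng, n)
            b = a + rng.normal(scale=0.4, size=a.shape)
            res = sp.kabsch(a, b)
            est, _ = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
            assert np.allclose(res.transform.rotation, est.as_matrix(),
                               atol=1e-8)


class TestPairCalpha:
    def test_chain_against_itself_covers_every_ca(self):
        model = sd.make_helix(8)
        chain = model.chains[0]
        fixed, mobile, pairing = sp.pair_calpha(chain, chain)
        assert len(pairing) == 8
        assert np.allclose(fixed, mobile)

    def test_deleted_residues_absent_from_pairing(self):
        model = sd.make_helix(10)
        target = model.copy()
        target.chains[0].residues = [
            r for r in target.chains[0].residues if r.number not in (4, 5, 6)]
        _f, _m, pairing = sp.pair_calpha(model.chains[0], target.chains[0])
        numbers = [r.number for r, _t in pairing]
        assert numbers == [1, 2, 3, 7, 8, 9, 10]

    def test_too_few_pairs_raise(self):
        a = sd.make_helix(4).chains[0]
        b = sd.make_helix(4, start_number=100).chains[0]
        with pytest.raises(ModelError):
            sp.pair_calpha(a, b)


class TestSuperposeAll:
    def test_template_alone_gives_single_zero_row(self):
        model = sd.make_helix(8)
        table, moved = sp.superpose_all(model.chains[0], [model])
        assert len(table) == 1
        assert table["rmsd_A"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_noise_set_rmsd_matches_manifest_and_histogram_sums(self):
        base = sd.make_helix(12)
        models, realized = [], []
        for seed in range(8):
            noisy, man = sd.perturb(base, "noise", seed=seed, sigma=0.4)
            noisy.entry_id = f"N{seed:03d}"
            models.append(noisy)
            realized.append(man.realized_rmsd)
        table, _ = sp.superpose_all(base.chains[0], models)
        # CA-only pairing differs from the all-atom manifest value by the
        # sampling of the same noise process; stay within a loose band
        assert table["rmsd_A"].mean() == pytest.approx(
            np.mean(realized), rel=0.35)
        hist = sp.rmsd_histogram(table["rmsd_A"])
        assert hist["count"].sum() == len(models)

    def test_planted_rigid_transform_recovered_exactly(self):
        base = sd.make_helix(10)
        moved, man = sd.perturb(base, "rigid", seed=2)
        moved.entry_id = "RIG1"
        table, transformed = sp.superpose_all(base.chains[0], [moved])
        assert table["rmsd_A"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        back = np.array([a.pos for a in transformed["RIG1"].all_atoms()])
        orig = np.array([a.pos for a in base.all_atoms()])
        assert np.allclose(back, orig, atol=1e-8)


class TestSelectionRmsd:
    def test_self_is_zero_for_all_selections(self, annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["tzd_head", "phenyl"])
        for sel in ("all-heavy", "heteroatoms"):
            rmsd, dists = sp.rmsd_on_selection(lig, lig, sel)
            assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_atom_distance_reported(self, annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["tzd_head", "phenyl"])
        other = lig.copy()
        other.atom("O20").pos = other.atom("O20").pos + np.array([1.0, 0, 0])
        _rmsd, dists = sp.rmsd_on_selection(lig, other, "all-heavy",
                                            superpose=False)
        assert dists["O20"] == pytest.approx(1.0)
        assert all(d == pytest.approx(0.0) for k, d in dists.items()
                   if k != "O20")

    def test_unmatched_atom_name_raises(self, annotated_ligand_factory):
        lig, _ = annotated_ligand_factory(["phenyl"])
        other = lig.copy()
        other.atoms[0].name = "CX"
        with pytest.raises(ModelError, match="C1"):
            sp.rmsd_on_selection(lig, other, "all-heavy")


def _ethane(offset_deg: float) -> LigandInstance:
    c1, c2 = np.zeros(3), np.array([1.54, 0.0, 0.0])
    atoms = [Atom("C1", "C", c1), Atom("C2", "C", c2)]
    for k, t in enumerate((0.0, 120.0, 240.0)):
        r = math.radians(t)
        atoms.append(Atom(f"H1{k}", "H",
                          c1 + np.array([-0.36, 1.01 * math.cos(r),
                                         1.01 * math.sin(r)])))
    for k, t in enumerate((0.0, 120.0, 240.0)):
        r = math.radians(t + offset_deg)
        atoms.append(Atom(f"H2{k}", "H",
                          c2 + np.array([0.36, 1.01 * math.cos(r),
                                         1.01 * math.sin(r)])))
    return sio.perceive_ligand_bonds(LigandInstance("ETH", "L", 1, atoms))


class TestRelaxation:
    def test_requires_perceived_bonds(self):
        lig = LigandInstance("X", "L", 1, [Atom("C1", "C", np.zeros(3))])
        with pytest.raises(ModelError, match="bonds"):
            sp.relax_ligand(lig)

    def test_near_eclipsed_ethane_relaxes_to_staggered(self):
        relaxed = sp.relax_ligand(_ethane(10.0))
        torsion = dihedral_deg(relaxed.atom("H10").pos, relaxed.atom("C1").pos,
                               relaxed.atom("C2").pos, relaxed.atom("H20").pos)
        assert min(abs(abs(torsion) - 60.0), abs(abs(torsion) - 180.0)) < 3.0

    def test_minimized_structure_is_a_fixed_point(self):
        once = sp.relax_ligand(_ethane(60.0))
        twice = sp.relax_ligand(once)
        shift = np.linalg.norm(
            np.array([a.pos for a in twice.atoms])
            - np.array([a.pos for a in once.atoms]), axis=1).max()
        assert shift < 0.05


def test_cross_complex_rmsd_matches_direct_computation(annotated_ligand_factory):
    rng = np.random.default_rng(9)
    template, _ = annotated_ligand_factory(["tzd_head", "phenyl"])
    copies = {}
    expected = {}
    for k in range(3):
        c = template.copy()
        noise = rng.normal(scale=0.1, size=(len(c.atoms), 3))
        for atom, dn in zip(c.atoms, noise):
            atom.pos = atom.pos + dn
        copies[f"E{k}"] = c
        names = [a.name for a in template.heavy_atoms]
        fixed = np.array([template.atom(n).pos for n in names])
        mobile = np.array([c.atom(n).pos for n in names])
        expected[f"E{k}"] = sp.kabsch(fixed, mobile).rmsd
    copies["GONE"] = None
    table = sp.ligand_cross_complex_rmsd("LIG", copies, template)
    by_acc = table.set_index("accession")
    for k, val in expected.items():
        assert by_acc.loc[k, "rmsd_A"] == pytest.approx(val, abs=1e-3)
    assert bool(by_acc.loc["GONE", "absent"])
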