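"""Seeded, manifest-backed synthetic fixtures.

Every fixture is a real PDB-format structure written through
:mod:`ppargpharm.structure_io`, together with a JSON manifest recording the
planted ground truth (pocket membership, hydrogen-bond geometries, rigid
transforms, noise levels, annotation-point counts).  The geometry is
idealised — ideal alpha-helices arranged radially around a fragment-built
ligand — which is enough to exercise distance/angle criteria exactly while
staying hand-checkable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .geometry import place_atom, rotation_about_axis, rotation_aligning, unit
from .model import (AA1_TO_3, Atom, Chain, LigandInstance, ModelError,
                    Residue, StructureModel)
from . import structure_io
from .superposition import RigidTransform, kabsch

__all__ = [
    "FixtureManifest", "ToyComplexSpec", "PocketContact", "HBondPlant",
    "WaterBridgePlant", "make_helix", "make_toy_complex", "perturb",
    "make_annotated_ligand", "write_fixture", "load_fixture",
    "helix_axis_stats", "FRAGMENT_LIBRARY",
]


class InfeasibleSpecError(ModelError):
    """Requested toy-complex geometry cannot be realised without clashes."""


# ---------------------------------------------------------------------------
# manifest

@dataclass
class FixtureManifest:
    seed: int = 0
    pocket: list[tuple[str, int]] = field(default_factory=list)
    hbonds: list[dict] = field(default_factory=list)
    water_bridges: list[dict] = field(default_factory=list)
    rotation: Optional[list[list[float]]] = None
    translation: Optional[list[float]] = None
    noise_sigma: float = 0.0
    realized_rmsd: Optional[float] = None
    annotation_counts: dict[str, int] = field(default_factory=dict)
    feature_vector: Optional[list[bool]] = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        data = dict(self.__dict__)
        data["pocket"] = [list(p) for p in self.pocket]
        return json.dumps(data, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        data = json.loads(text)
        data["pocket"] = [tuple(p) for p in data.get("pocket", [])]
        return cls(**data)


def write_fixture(directory: Union[str, Path], model: StructureModel,
                  manifest: FixtureManifest) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "model.pdb").write_text(structure_io.write_pdb(model))
    (d / "manifest.json").write_text(manifest.to_json() + "\n")


def load_fixture(directory: Union[str, Path]
                 ) -> tuple[StructureModel, FixtureManifest]:
    d = Path(directory)
    model = structure_io.read_pdb(d / "model.pdb")
    manifest = FixtureManifest.from_json((d / "manifest.json").read_text())
    return model, manifest


# ---------------------------------------------------------------------------
# ideal helix builder

# backbone geometry: bond lengths (A) and angles (deg) of the peptide unit
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0

# side-chain recipes: atom -> (frame atoms a,b,c, bond, angle, torsion)
# torsions marked "chi1"/"chi2" are replaced by the default rotamer below
_SIDECHAINS: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, "chi1")],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 114.4, "chi1")],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, "chi1"),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, "chi1-120")],
    "VAL": [("CG1", "C", ("N", "CA", "CB"), 1.527, 110.7, "chi1"),
            ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.7, "chi1-120")],
    "LEU": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, "chi1"),
            ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, 60.0)],
    "MET": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
            ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
            ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, 180.0)],
    "ASP": [("CG", "C", ("N", "CA", "CB"), 1.516, 113.1, "chi1"),
            ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, 0.0),
            ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, 180.0)],
    "ASN": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.7, "chi1"),
            ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, 0.0),
            ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, 180.0)],
    "GLU": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
            ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, 180.0)],
    "GLN": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
            ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, 180.0)],
    "LYS": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
            ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, 180.0)],
    "ARG": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
            ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
            ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, "chi1"),
            ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, "chi2"),
            ("CD2", "C", ("CA", "CB", "CG"), 1.354, 129.7, "chi2+180"),
            ("CE1", "C", ("CB", "CG", "ND1"), 1.321, 109.0, 180.0),
            ("NE2", "N", ("CG", "ND1", "CE1"), 1.310, 111.7, 0.0)],
    "PHE": [("CG", "C", ("N", "CA", "CB"), 1.512, 113.9, "chi1"),
            ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, "chi2"),
            ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, "chi2+180"),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.389, 121.2, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.389, 121.2, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.389, 119.6, 0.0)],
    "TYR": [("CG", "C", ("N", "CA", "CB"), 1.512, 113.9, "chi1"),
            ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, "chi2"),
            ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, "chi2+180"),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.389, 121.2, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.389, 121.2, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.389, 119.6, 0.0),
            ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
}
_DEFAULT_CHI1 = -65.0
_DEFAULT_CHI2 = 90.0

#: side-chain atom used as the planted contact for each residue type
CONTACT_ATOMS = {
    "SER": "OG", "THR": "OG1", "CYS": "SG", "TYR": "OH", "HIS": "NE2",
    "LYS": "NZ", "ARG": "NH1", "ASP": "OD1", "GLU": "OE1", "ASN": "OD1",
    "GLN": "OE1",
}
#: heavy-atom anchor bonded to the contact atom (for H-bond cone geometry)
_CONTACT_ANCHORS = {
    "OG": "CB", "OG1": "CB", "SG": "CB", "OH": "CZ", "NE2": "CE1",
    "NZ": "CE", "NH1": "CZ", "OD1": "CG", "OE1": "CD",
}


def _resolve_torsion(spec, chi1: float, chi2: float) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    value = {"chi1": chi1, "chi2": chi2}[spec[:4]]
    rest = spec[4:]
    return value + float(rest) if rest else value


def _normalise_sequence(n_res: int, sequence) -> list[str]:
    if sequence is None:
        return ["ALA"] * n_res
    if isinstance(sequence, str):
        codes = []
        for ch in sequence.upper():
            if ch not in AA1_TO_3:
                raise ModelError(f"unknown residue code {ch!r}")
            codes.append(AA1_TO_3[ch])
    else:
        codes = [str(c).upper() for c in sequence]
    if len(codes) != n_res:
        raise ModelError("sequence length does not match n_res")
    for code in codes:
        if code not in _SIDECHAINS:
            raise ModelError(f"residue type {code!r} not in the helix builder "
                             f"library ({sorted(_SIDECHAINS)})")
    return codes


def make_helix(n_res: int, sequence=None, chain_id: str = "A",
               start_number: int = 1) -> StructureModel:
    """Ideal alpha-helix (phi=-57, psi=-47) with idealised side-chain rotamers.

    ``sequence`` may be a one-letter string or a list of three-letter codes;
    the default is poly-alanine.  Residues are numbered consecutively from
    ``start_number``.
    """
    if n_res < 4:
        raise ModelError("a helix needs at least 4 residues")
    codes = _normalise_sequence(n_res, sequence)

    backbone: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    backbone.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = backbone[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI)
        ca = place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, _PHI)
        backbone.append({"N": n, "CA": ca, "C": c})

    chain = Chain(chain_id, [])
    for i, code in enumerate(codes):
        bb = backbone[i]
        pos = dict(bb)
        pos["O"] = place_atom(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O,
                              _PSI + 180.0)
        if code != "GLY":
            # tetrahedral C-beta on the L-configuration side
            b1 = unit(bb["N"] - bb["CA"])
            b2 = unit(bb["C"] - bb["CA"])
            bis = -unit(b1 + b2)
            perp = unit(np.cross(b2, b1))
            direction = math.cos(math.radians(54.75)) * bis \
                + math.sin(math.radians(54.75)) * perp
            pos["CB"] = bb["CA"] + 1.530 * direction
        for (name, element, frame, bond, angle, torsion) in _SIDECHAINS[code]:
            a, b, c = (pos[f] for f in frame)
            tor = _resolve_torsion(torsion, _DEFAULT_CHI1, _DEFAULT_CHI2)
            pos[name] = place_atom(a, b, c, bond, angle, tor)
        # atom-name first character is the element for every name used here
        atoms = [Atom(nm, nm[0], p) for nm, p in pos.items()]
        res = Residue(code, start_number + i, "", chain_id, atoms)
        chain.residues.append(res)
    chain.residues.sort(key=lambda r: (r.number, r.icode))
    return StructureModel(entry_id="HELIX", chains=[chain])


def helix_axis_stats(ca_coords: np.ndarray) -> dict[str, float]:
    """Rise per residue and residues per turn, from a least-squares axis."""
    ca = np.asarray(ca_coords, dtype=float)
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    proj = (ca - center) @ axis
    if proj[-1] < proj[0]:
        axis, proj = -axis, -proj
    rise = float(np.mean(np.diff(proj)))
    radial = ca - center - np.outer(proj, axis)
    e1 = unit(radial[0])
    e2 = np.cross(axis, e1)
    angles = np.unwrap(np.arctan2(radial @ e2, radial @ e1))
    per_turn = float(2 * np.pi / np.mean(np.diff(angles)))
    return {"rise": rise, "residues_per_turn": abs(per_turn)}


# ---------------------------------------------------------------------------
# fragment-built ligands

def _hexagon(radius: float = 1.395) -> np.ndarray:
    pts = []
    for k in range(6):
        t = math.radians(60 * k)
        pts.append([radius - radius * math.cos(t), radius * math.sin(t), 0.0])
    return np.array(pts)  # C1 at origin, ring extending +x


def _pentagon(side: float = 1.60) -> np.ndarray:
    radius = side / (2 * math.sin(math.pi / 5))
    pts = []
    for k in range(5):
        t = math.radians(72 * k)
        pts.append([radius - radius * math.cos(t), radius * math.sin(t), 0.0])
    return np.array(pts)


def _fragment_phenyl() -> dict:
    ring = _hexagon()
    center = ring.mean(axis=0)
    atoms = [(f"C{i+1}", "C", ring[i], 0) for i in range(6)]
    hydrogens = []
    for i in (1, 2, 4, 5):  # ortho/meta positions; C1=attach_in, C4=attach_out
        direction = unit(ring[i] - center)
        hydrogens.append((f"H{i+1}", "H", ring[i] + 1.08 * direction, 0))
    bonds = [(i, (i + 1) % 6, 1, True) for i in range(6)]
    nb = len(atoms)
    for k, (i, *_r) in enumerate([(1,), (2,), (4,), (5,)]):
        bonds.append((i, nb + k, 1, False))
    return {
        "atoms": atoms + hydrogens, "bonds": bonds,
        "attach_in": 0, "attach_out": 3,
        "hydrophobic": [0, 1, 2, 3, 4, 5],
        "counts": {"Don": 0, "Acc": 0, "Cat": 0, "Ani": 0, "Aro": 1,
                   "PiR": 1, "HydA": 6, "Don2": 0, "Acc2": 0},
    }


def _fragment_alkyl(n: int = 3) -> dict:
    atoms, bonds, hydro = [], [], []
    for i in range(n):
        x = 1.25 * i
        y = 0.5 if i % 2 else 0.0
        atoms.append((f"C{i+1}", "C", np.array([x, y, 0.0]), 0))
        if i:
            bonds.append((i - 1, i, 1, False))
        hydro.append(i)
    nb = len(atoms)
    h = 0
    for i in range(n):
        base = np.asarray(atoms[i][2])
        for dz in (1.0, -1.0):
            atoms.append((f"H{h+1}", "H", base + np.array([0.0, -0.4 * dz, dz]), 0))
            bonds.append((i, nb + h, 1, False))
            h += 1
    return {
        "atoms": atoms, "bonds": bonds, "attach_in": 0, "attach_out": n - 1,
        "hydrophobic": hydro,
        "counts": {"Don": 0, "Acc": 0, "Cat": 0, "Ani": 0, "Aro": 0,
                   "PiR": 0, "HydA": n, "Don2": 0, "Acc2": 0},
    }


def _fragment_methane() -> dict:
    atoms = [("C1", "C", np.zeros(3), 0)]
    t = 1.09 / math.sqrt(3)
    for k, sgn in enumerate([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]):
        atoms.append((f"H{k+1}", "H", t * np.array(sgn, dtype=float), 0))
    bonds = [(0, k + 1, 1, False) for k in range(4)]
    return {
        "atoms": atoms, "bonds": bonds, "attach_in": 0, "attach_out": 0,
        "hydrophobic": [0],
        "counts": {"Don": 0, "Acc": 0, "Cat": 0, "Ani": 0, "Aro": 0,
                   "PiR": 0, "HydA": 1, "Don2": 0, "Acc2": 0},
    }


def _fragment_carboxylate() -> dict:
    # C at origin; two equivalent oxygens; group charge -1 on O2
    atoms = [
        ("C1", "C", np.zeros(3), 0),
        ("O1", "O", np.array([0.63, 1.08, 0.0]), 0),
        ("O2", "O", np.array([0.63, -1.08, 0.0]), -1),
    ]
    bonds = [(0, 1, 2, False), (0, 2, 1, False)]
    return {
        "atoms": atoms, "bonds": bonds, "attach_in": 0, "attach_out": 0,
        "hydrophobic": [],
        "counts": {"Don": 0, "Acc": 2, "Cat": 0, "Ani": 1, "Aro": 0,
                   "PiR": 0, "HydA": 0, "Don2": 0, "Acc2": 2},
    }


def _fragment_hydroxyl() -> dict:
    atoms = [("O1", "O", np.zeros(3), 0),
             ("HO1", "H", np.array([0.32, 0.91, 0.0]), 0)]
    return {
        "atoms": atoms, "bonds": [(0, 1, 1, False)],
        "attach_in": 0, "attach_out": 0, "hydrophobic": [],
        "counts": {"Don": 1, "Acc": 1, "Cat": 0, "Ani": 0, "Aro": 0,
                   "PiR": 0, "HydA": 0, "Don2": 1, "Acc2": 1},
    }


def _fragment_amide() -> dict:
    atoms = [
        ("C1", "C", np.zeros(3), 0),
        ("O1", "O", np.array([0.61, 1.06, 0.0]), 0),
        ("N1", "N", np.array([0.66, -1.14, 0.0]), 0),
        ("HN1", "H", np.array([1.67, -1.16, 0.0]), 0),
        ("HN2", "H", np.array([0.17, -2.01, 0.0]), 0),
    ]
    bonds = [(0, 1, 2, False), (0, 2, 1, False), (2, 3, 1, False),
             (2, 4, 1, False)]
    return {
        "atoms": atoms, "bonds": bonds, "attach_in": 0, "attach_out": 0,
        "hydrophobic": [],
        "counts": {"Don": 1, "Acc": 1, "Cat": 0, "Ani": 0, "Aro": 0,
                   "PiR": 0, "HydA": 0, "Don2": 2, "Acc2": 1},
    }


def _fragment_amine() -> dict:
    # methylammonium-like: attach carbon plus protonated N
    atoms = [
        ("C1", "C", np.zeros(3), 0),
        ("N1", "N", np.array([1.49, 0.0, 0.0]), 1),
        ("HN1", "H", np.array([1.86, 0.95, 0.0]), 0),
        ("HN2", "H", np.array([1.86, -0.48, 0.83]), 0),
        ("HN3", "H", np.array([1.86, -0.48, -0.83]), 0),
    ]
    bonds = [(0, 1, 1, False), (1, 2, 1, False), (1, 3, 1, False),
             (1, 4, 1, False)]
    return {
        "atoms": atoms, "bonds": bonds, "attach_in": 0, "attach_out": 0,
        "hydrophobic": [],
        "counts": {"Don": 1, "Acc": 0, "Cat": 1, "Ani": 0, "Aro": 0,
                   "PiR": 0, "HydA": 0, "Don2": 3, "Acc2": 0},
    }


def _fragment_tzd_head() -> dict:
    """Thiazolidine-2,4-dione head group: ring S1-C2(=O2)-N3(H)-C4(=O4)-C5."""
    ring = _pentagon()
    center = ring.mean(axis=0)
    # attach through C5 (the exocyclic-methylidene carbon in glitazones)
    s1, c2, n3, c4, c5 = ring[2], ring[1], ring[0], ring[4], ring[3]
    atoms = [
        ("S1", "S", s1, 0), ("C2", "C", c2, 0), ("N3", "N", n3, 0),
        ("C4", "C", c4, 0), ("C5", "C", c5, 0),
        ("O2", "O", c2 + 1.22 * unit(c2 - center), 0),
        ("O4", "O", c4 + 1.22 * unit(c4 - center), 0),
        ("HN3", "H", n3 + 1.01 * unit(n3 - center), 0),
        ("H51", "H", c5 + np.array([0.4, 0.2, 0.95]), 0),
    ]
    bonds = [(0, 1, 1, False), (1, 2, 1, False), (2, 3, 1, False),
             (3, 4, 1, False), (4, 0, 1, False), (1, 5, 2, False),
             (3, 6, 2, False), (2, 7, 1, False), (4, 8, 1, False)]
    return {
        "atoms": atoms, "bonds": bonds, "attach_in": 4, "attach_out": 4,
        "hydrophobic": [4],  # C5: neighbours S/C/H only
        "counts": {"Don": 1, "Acc": 2, "Cat": 0, "Ani": 0, "Aro": 0,
                   "PiR": 0, "HydA": 1, "Don2": 1, "Acc2": 2},
    }


FRAGMENT_LIBRARY = {
    "phenyl": _fragment_phenyl,
    "alkyl": _fragment_alkyl,
    "methane": _fragment_methane,
    "carboxylate": _fragment_carboxylate,
    "hydroxyl": _fragment_hydroxyl,
    "amide": _fragment_amide,
    "amine": _fragment_amine,
    "tzd_head": _fragment_tzd_head,
}


def make_annotated_ligand(
    fragments: Sequence[str],
    anchors: Optional[Sequence[np.ndarray]] = None,
    comp_id: str = "LIG",
) -> tuple[LigandInstance, FixtureManifest]:
    """Assemble a 3D ligand from parameterised fragments.

    Fragments are chained head-to-tail with 1.5 A single bonds, or — when
    ``anchors`` is given — each fragment is translated so its heavy-atom
    centroid sits on the corresponding anchor point (no inter-fragment
    bonds; used to plant ligands at pharmacophore feature centroids).  The
    manifest records the expected annotation-point count per kind.
    """
    if not fragments:
        raise ModelError("at least one fragment required")
    frag_data = []
    for name in fragments:
        if name not in FRAGMENT_LIBRARY:
            raise ModelError(f"unknown fragment {name!r}; known: "
                             f"{sorted(FRAGMENT_LIBRARY)}")
        frag_data.append(FRAGMENT_LIBRARY[name]())
    if anchors is not None and len(anchors) != len(frag_data):
        raise ModelError("anchors must match the number of fragments")

    atoms: list[Atom] = []
    bonds: list = []
    charges: dict[int, int] = {}
    hydro_global: list[int] = []
    junctions: list[tuple[int, int]] = []
    offset = 0
    cursor = np.zeros(3)
    prev_out_global = None
    for k, frag in enumerate(frag_data):
        local = np.array([np.asarray(p) for (_n, _e, p, _q) in frag["atoms"]])
        if anchors is not None:
            heavy = [i for i, (_n, e, _p, _q) in enumerate(frag["atoms"])
                     if e != "H"]
            shift = np.asarray(anchors[k], dtype=float) - local[heavy].mean(axis=0)
        else:
            attach_in_pos = local[frag["attach_in"]]
            shift = cursor - attach_in_pos
        placed = local + shift
        for i, (name, element, _pos, q) in enumerate(frag["atoms"]):
            atoms.append(Atom(f"{name}{k}" if len(frag_data) > 1 else name,
                              element, placed[i]))
            if q:
                charges[offset + i] = q
        for (i, j, order, arom) in frag["bonds"]:
            bonds.append((offset + i, offset + j, order, arom))
        hydro_global.extend(offset + i for i in frag["hydrophobic"])
        if anchors is None and prev_out_global is not None:
            bonds.append((prev_out_global, offset + frag["attach_in"], 1, False))
            junctions.append((prev_out_global, offset + frag["attach_in"]))
        prev_out_global = offset + frag["attach_out"]
        cursor = placed[frag["attach_out"]] + np.array([1.5, 0.0, 0.0])
        offset += len(frag["atoms"])

    ligand = LigandInstance(comp_id, "L", 900, atoms, bonds, charges)

    counts: dict[str, int] = {}
    for frag in frag_data:
        for kind, n in frag["counts"].items():
            counts[kind] = counts.get(kind, 0) + n
    counts["Hyd"] = _expected_hyd_clusters(hydro_global, bonds)
    counts["Cat"] = sum(f["counts"]["Cat"] for f in frag_data)

    manifest = FixtureManifest(annotation_counts=counts,
                               extras={"fragments": list(fragments)})
    return ligand, manifest


def _expected_hyd_clusters(hydro: list[int], bonds: list) -> int:
    """Expected hydrophobic-centroid count: bond-graph connected components
    restricted to hydrophobic atoms (independent of the distance-linkage
    clustering used by the annotator)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(hydro)
    hydro_set = set(hydro)
    for i, j, *_ in bonds:
        if i in hydro_set and j in hydro_set:
            g.add_edge(i, j)
    return nx.number_connected_components(g) if hydro else 0


# ---------------------------------------------------------------------------
# toy complexes

@dataclass
class PocketContact:
    resname: str = "LEU"
    distance: float = 4.0
    ligand_atom: Optional[str] = None


@dataclass
class HBondPlant:
    resname: str = "SER"
    role: str = "donor"       # protein side: donor or acceptor
    ligand_atom: str = ""
    distance: float = 2.8


@dataclass
class WaterBridgePlant:
    resname: str = "SER"
    ligand_atom: str = ""
    d_ligand: float = 2.8
    d_protein: float = 2.8


@dataclass
class ToyComplexSpec:
    ligand_fragments: tuple[str, ...] = ("tzd_head", "phenyl", "alkyl")
    pocket: tuple[PocketContact, ...] = ()
    hbonds: tuple[HBondPlant, ...] = ()
    water_bridges: tuple[WaterBridgePlant, ...] = ()
    decoys: int = 2
    cutoff: float = 4.5


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def _ligand_atom_or_nearest(ligand: LigandInstance, name: Optional[str],
                            direction: np.ndarray) -> Atom:
    if name:
        atom = ligand.atom(name)
        if atom is None:
            raise ModelError(f"ligand atom {name!r} not found")
        return atom
    heavy = ligand.heavy_atoms
    center = ligand.centroid
    scores = [float(np.dot(a.pos - center, direction)) for a in heavy]
    return heavy[int(np.argmax(scores))]


def _build_contact_helix(resname: str, number_base: int) -> StructureModel:
    # glycine flanks keep the helix slim so that only the centre residue
    # can reach inside the pocket cutoff
    seq = ["GLY", "GLY", resname, "GLY", "GLY"]
    return make_helix(5, seq, chain_id="A", start_number=number_base)


def _place_helix(helix: StructureModel, contact_atom: Atom,
                 anchor_atom: Optional[Atom], target: np.ndarray,
                 away: np.ndarray, spin_deg: float,
                 cone_angle: float = 109.5,
                 azimuth_deg: float = 0.0) -> StructureModel:
    """Rigidly place a helix so its contact atom sits on ``target``.

    The bond direction anchor->contact is oriented at ``cone_angle`` degrees
    from the outward direction so that a staggered -OH/-SH rotamer can point
    straight back at the ligand; the helix body is spun about that bond
    axis by ``spin_deg`` (the free parameter of the placement search).
    """
    moved = helix.copy()
    coords_atoms = moved.all_atoms()
    coords = np.array([a.pos for a in coords_atoms])
    c = contact_atom.pos.copy()

    if anchor_atom is not None:
        bond_dir = unit(c - anchor_atom.pos)
        w1 = np.cross(away, [0.0, 0.0, 1.0])
        if np.linalg.norm(w1) < 1e-6:
            w1 = np.cross(away, [0.0, 1.0, 0.0])
        w1 = unit(w1)
        w2 = np.cross(away, w1)
        az = math.radians(azimuth_deg)
        w = math.cos(az) * w1 + math.sin(az) * w2
        ca, sa = math.cos(math.radians(cone_angle)), math.sin(math.radians(cone_angle))
        target_bond = ca * away + sa * w
        rot1 = rotation_aligning(bond_dir, target_bond)
    else:
        centroid = coords.mean(axis=0)
        rot1 = rotation_aligning(unit(c - centroid), -away)
        target_bond = away
    coords = (coords - c) @ rot1.T

    spin = rotation_about_axis(target_bond, spin_deg)
    coords = coords @ spin.T + target
    for atom, p in zip(coords_atoms, coords):
        atom.pos = p
    return moved


_OH_FRAMES = {  # resname -> (contact, anchor, frame atom, O-H/S-H length)
    "SER": ("OG", "CB", "CA", 0.96),
    "THR": ("OG1", "CB", "CA", 0.96),
    "TYR": ("OH", "CZ", "CE1", 0.96),
    "CYS": ("SG", "CB", "CA", 1.34),
}


def _donor_rotamer_viable(res: Residue, lig_pos: np.ndarray,
                          acceptors: list[np.ndarray],
                          min_angle: float = 125.0) -> bool:
    """True when the rotamer the protonation module will actually select
    (maximum satisfied hydrogen bonds, ties to the lowest torsion) points
    its hydrogen at the planted ligand atom with D-H...A >= ``min_angle``.
    """
    if res.name not in _OH_FRAMES:
        return True  # fixed-H donors checked implicitly by geometry
    contact_nm, anchor_nm, frame_nm, bond = _OH_FRAMES[res.name]
    contact, anchor, frame = (res.atom(contact_nm), res.atom(anchor_nm),
                              res.atom(frame_nm))
    if None in (contact, anchor, frame):
        return False
    from .geometry import angle_deg
    from .protonation import _count_hbonds_for_h

    best = None
    for torsion in sorted((-60.0, 60.0, 180.0)):
        h = place_atom(frame.pos, anchor.pos, contact.pos, bond, 109.5, torsion)
        n_hb = _count_hbonds_for_h(h, contact.pos, acceptors)
        if best is None or n_hb > best[0]:
            best = (n_hb, h)
    return angle_deg(contact.pos, best[1], lig_pos) >= min_angle


def _aligned_spins(helix: StructureModel, center_num: int, resname: str,
                   contact: Atom, anchor: Atom, target: np.ndarray,
                   u: np.ndarray, lig_pos: np.ndarray) -> list[tuple[float, float]]:
    """Spin angles (per cone azimuth) that point a staggered hydroxyl/thiol
    rotamer exactly at the planted ligand atom.

    The spin rotates the helix about the anchor-contact bond axis, so the
    hydrogen-frame torsion varies linearly with it; two probe placements
    give the slope and each target torsion is then solved directly.
    """
    from .geometry import dihedral_deg

    _c, anchor_nm, frame_nm, _b = _OH_FRAMES[resname]
    contact_nm = _OH_FRAMES[resname][0]
    out: list[tuple[float, float]] = []
    for az in range(0, 360, 30):
        def torsion_at(spin: float) -> float:
            placed = _place_helix(helix, contact, anchor, target, u, spin,
                                  azimuth_deg=float(az))
            cres = placed.chains[0].residue(center_num)
            return dihedral_deg(cres.atom(frame_nm).pos,
                                cres.atom(anchor_nm).pos,
                                cres.atom(contact_nm).pos, lig_pos)

        t0 = torsion_at(0.0)
        diff = ((torsion_at(20.0) - t0 + 180.0) % 360.0) - 180.0
        slope = 1.0 if diff > 0 else -1.0
        for tau in (-60.0, 180.0, 60.0):  # tie-winning rotamer first
            out.append(((slope * (tau - t0)) % 360.0, float(az)))
    return out


def _ligand_polar_positions(ligand: LigandInstance) -> np.ndarray:
    pts = [a.pos for a in ligand.heavy_atoms if a.element in ("N", "O", "S")]
    return np.array(pts) if pts else np.zeros((0, 3))


def make_toy_complex(spec: ToyComplexSpec, seed: int = 0,
                     max_restarts: int = 8
                     ) -> tuple[StructureModel, FixtureManifest]:
    """Arrange short ideal helices around a fragment-built ligand so that
    exactly the specified pocket residues, hydrogen bonds and water bridges
    are planted; the manifest records all ground truth.

    The seeded direction search restarts with derived sub-seeds when an
    arrangement dead-ends (the whole procedure stays deterministic per
    seed); :class:`InfeasibleSpecError` is raised only when every restart
    fails.
    """
    last: Optional[InfeasibleSpecError] = None
    for restart in range(max_restarts):
        try:
            model, manifest = _make_toy_complex_once(
                spec, seed + restart * 1000003)
            manifest.seed = seed
            return model, manifest
        except InfeasibleSpecError as exc:
            last = exc
    raise last


def _make_toy_complex_once(spec: ToyComplexSpec, seed: int
                           ) -> tuple[StructureModel, FixtureManifest]:
    rng = np.random.default_rng(seed)
    # fragment-defined bonds/charges are authoritative for the planted ligand
    ligand, lig_manifest = make_annotated_ligand(spec.ligand_fragments)

    items: list[tuple[str, object]] = []
    items += [("pocket", p) for p in spec.pocket]
    items += [("hbond", h) for h in spec.hbonds]
    items += [("water", w) for w in spec.water_bridges]

    n_dirs = max(2 * (len(items) + spec.decoys) + 6, 14)
    directions = _fibonacci_sphere(n_dirs)
    directions = directions[rng.permutation(n_dirs)]
    spins = [k * 5.0 for k in range(72)]

    lig_heavy = ligand.coords(heavy_only=True)
    lig_polar = _ligand_polar_positions(ligand)
    model = StructureModel(entry_id=f"TOY{seed % 10000:04d}")
    chain = Chain("A", [])
    model.chains.append(chain)
    model.het_groups.append(ligand)

    manifest = FixtureManifest(seed=seed,
                               annotation_counts=lig_manifest.annotation_counts,
                               extras={"ligand_fragments": list(spec.ligand_fragments)})

    ctx = {
        "lig_heavy": lig_heavy, "lig_polar": lig_polar,
        "helices": [], "waters": [], "cutoff": spec.cutoff,
    }
    number_base = 101
    dir_idx = 0

    def accept(placed: StructureModel, water_pos: Optional[np.ndarray]) -> None:
        ctx["helices"].append(placed)
        chain.residues.extend(r.copy() for r in placed.chains[0].residues)
        if water_pos is not None:
            ctx["waters"].append(water_pos)

    def place_item(kind: str, item) -> None:
        nonlocal number_base, dir_idx
        resname = item.resname.upper()
        if kind == "hbond" and item.role == "acceptor":
            lig_atom = ligand.atom(item.ligand_atom)
            if lig_atom is None:
                raise ModelError(f"ligand atom {item.ligand_atom!r} absent")
            h_idx = [j for j in ligand.neighbors(
                ligand.atom_index(item.ligand_atom))
                if ligand.atoms[j].is_hydrogen]
            if not h_idx:
                raise ModelError(
                    f"ligand atom {item.ligand_atom!r} has no hydrogen; an "
                    "acceptor-role plant needs a ligand donor")
            forced_u = unit(ligand.atoms[h_idx[0]].pos - lig_atom.pos)
            candidates = [forced_u]
        else:
            candidates = [directions[(dir_idx + k) % n_dirs]
                          for k in range(n_dirs)]
            # fall back to finer seeded sampling when the coarse fan fails
            extra = rng.normal(size=(60, 3))
            candidates += list(extra / np.linalg.norm(extra, axis=1)[:, None])

        helix = _build_contact_helix(resname, number_base)
        center_res = helix.chains[0].residue(number_base + 2)
        contact_name = CONTACT_ATOMS.get(resname, "CB")
        contact = center_res.atom(contact_name) \
            or center_res.atom("CB") or center_res.atom("CA")
        anchor_name = _CONTACT_ANCHORS.get(contact.name)
        anchor = center_res.atom(anchor_name) if anchor_name else None

        for u in candidates:
            water_pos = None
            if kind == "pocket":
                lig_atom = _ligand_atom_or_nearest(ligand, item.ligand_atom, u)
                target = lig_atom.pos + item.distance * u
            elif kind == "hbond":
                lig_atom = ligand.atom(item.ligand_atom)
                if lig_atom is None:
                    raise ModelError(f"ligand atom {item.ligand_atom!r} absent")
                target = lig_atom.pos + item.distance * u
            else:  # water bridge
                lig_atom = ligand.atom(item.ligand_atom)
                if lig_atom is None:
                    raise ModelError(f"ligand atom {item.ligand_atom!r} absent")
                water_pos = lig_atom.pos + item.d_ligand * u
                if not _water_position_ok(water_pos, lig_atom.pos, ctx):
                    continue  # direction itself is bad; try the next one
                target = water_pos + item.d_protein * u

            if kind == "hbond" and item.role == "donor" \
                    and resname in _OH_FRAMES and anchor is not None:
                # 2-DOF search: cone azimuth free, spin solved so that a
                # staggered rotamer points straight at the ligand atom
                placements = _aligned_spins(helix, number_base + 2, resname,
                                            contact, anchor, target, u,
                                            lig_atom.pos)
            else:
                placements = [(s, az) for az in (0.0, 90.0, 180.0, 270.0)
                              for s in range(0, 360, 15)]

            for spin, azimuth in placements:
                placed = _place_helix(helix, contact, anchor, target, u, spin,
                                      azimuth_deg=azimuth)
                center_placed = placed.chains[0].residue(number_base + 2)
                exempt = (number_base + 2, contact.name,
                          lig_atom.pos if kind == "hbond" else None,
                          water_pos)
                if not _arrangement_ok(placed, ctx, kind, item, exempt):
                    continue
                if kind == "hbond" and item.role == "donor":
                    env = [np.asarray(p) for p in ctx["lig_polar"]]
                    # intra-residue atoms never score as rotamer partners
                    env += [a.pos for other in ctx["helices"] + [placed]
                            for r in other.chains[0].residues
                            for a in r.atoms
                            if a.element in ("N", "O", "S")
                            and r.number != number_base + 2]
                    env += list(ctx["waters"])
                    if not _donor_rotamer_viable(center_placed, lig_atom.pos,
                                                 env):
                        continue

                accept(placed, water_pos)
                center_key = (resname, number_base + 2)
                if kind == "pocket" or (kind == "hbond"
                                        and item.distance <= spec.cutoff):
                    manifest.pocket.append(center_key)
                if kind == "hbond":
                    manifest.hbonds.append({
                        "resname": resname, "resnum": number_base + 2,
                        "protein_atom": contact.name, "role": item.role,
                        "ligand_atom": lig_atom.name,
                        "distance": item.distance,
                    })
                if kind == "water":
                    water = Residue("HOH", 5001 + len(model.waters), "", "W",
                                    [Atom("O", "O", water_pos)])
                    model.waters.append(water)
                    manifest.water_bridges.append({
                        "resname": resname, "resnum": number_base + 2,
                        "protein_atom": contact.name,
                        "ligand_atom": lig_atom.name,
                        "water_number": water.number,
                        "d_ligand": item.d_ligand,
                        "d_protein": item.d_protein,
                    })
                number_base += 100
                dir_idx += 1
                return
        raise InfeasibleSpecError(
            f"could not place {kind} residue {item.resname} without clashes")

    for kind, item in items:
        place_item(kind, item)

    # decoy helices, guaranteed outside the pocket cutoff
    for _ in range(spec.decoys):
        for attempt in range(n_dirs * 4):
            u = directions[(dir_idx + attempt) % n_dirs]
            helix = _build_contact_helix("LEU", number_base)
            center_res = helix.chains[0].residue(number_base + 2)
            contact = center_res.atom("CB")
            target = ligand.centroid + (spec.cutoff + 8.0) * u
            placed = _place_helix(helix, contact, None, target, u, 0.0)
            if _arrangement_ok(placed, ctx, "decoy", None,
                               (None, None, None, None)):
                accept(placed, None)
                number_base += 100
                dir_idx += 1
                break
        else:
            raise InfeasibleSpecError("could not place decoy helix")

    chain.residues.sort(key=lambda r: (r.number, r.icode))
    manifest.pocket.sort()
    manifest.feature_vector = None
    _verify_planted_pocket(model, ligand, manifest, spec.cutoff)
    return model, manifest


_POLAR_EXCLUSION = 3.65    # A, spurious polar-contact guard
_WATER_EXCLUSION = 3.8     # A, helix atoms vs existing waters
_CLASH = 2.2               # A, hard-sphere clash


def _water_position_ok(water_pos: np.ndarray, target_lig_pos: np.ndarray,
                       ctx: dict) -> bool:
    """Water must bridge only its intended ligand atom and protein partner."""
    for pos in ctx["lig_polar"]:
        if np.allclose(pos, target_lig_pos):
            continue
        if np.linalg.norm(pos - water_pos) < _POLAR_EXCLUSION:
            return False
    for other in ctx["helices"]:
        for res in other.chains[0].residues:
            for a in res.atoms:
                d = float(np.linalg.norm(a.pos - water_pos))
                if a.element in ("N", "O", "S") and d < _POLAR_EXCLUSION:
                    return False
                if d < _CLASH:
                    return False
    for w in ctx["waters"]:
        if np.linalg.norm(w - water_pos) < _POLAR_EXCLUSION:
            return False
    return True


def _arrangement_ok(placed: StructureModel, ctx: dict, kind: str, item,
                    exempt: tuple) -> bool:
    """Clash/exclusion tests for one candidate helix placement.

    Beyond hard-sphere clashes, every protein polar atom must stay clear of
    every ligand polar atom (and of planted waters) except the single
    planted contact pair, so detected interactions equal planted ones.
    """
    cutoff = ctx["cutoff"]
    lig_heavy = ctx["lig_heavy"]
    lig_polar = ctx["lig_polar"]
    exempt_resnum, exempt_atom, exempt_lig_pos, own_water = exempt
    # the geometry is deterministic, so a small strict clearance beyond the
    # cutoff is enough to keep non-planted residues out of the pocket
    margin = 0.05
    for res in placed.chains[0].residues:
        heavy = np.array([a.pos for a in res.heavy_atoms])
        dmin = float(np.min(np.linalg.norm(
            heavy[:, None, :] - lig_heavy[None, :, :], axis=2)))
        is_center = (res.number == exempt_resnum) if exempt_resnum \
            else False
        if kind == "pocket" and item is not None \
                and res.number == placed.chains[0].residues[2].number:
            if not (item.distance - 0.45 <= dmin <= cutoff - margin):
                return False
        elif kind == "hbond" and item is not None \
                and res.number == placed.chains[0].residues[2].number:
            if dmin < _CLASH:
                return False
        else:
            if dmin < cutoff + margin:
                return False
        # spurious polar contacts
        for a in res.atoms:
            if a.element not in ("N", "O", "S"):
                continue
            for pos in lig_polar:
                if exempt_lig_pos is not None and a.name == exempt_atom \
                        and res.number == exempt_resnum \
                        and np.allclose(pos, exempt_lig_pos):
                    continue
                if np.linalg.norm(a.pos - pos) < _POLAR_EXCLUSION:
                    return False
        # keep clear of planted waters (own bridge contact pair exempt)
        for w in ctx["waters"] + ([own_water] if own_water is not None else []):
            for a in res.atoms:
                own_pair = (own_water is not None and w is own_water
                            and a.name == exempt_atom
                            and res.number == exempt_resnum)
                if own_pair:
                    continue
                d = float(np.linalg.norm(a.pos - w))
                limit = _WATER_EXCLUSION if a.element in ("N", "O", "S") \
                    else _CLASH
                if d < limit:
                    return False
    new_coords = np.array([a.pos for a in placed.all_atoms()
                           if not a.is_hydrogen])
    new_polar = np.array([a.pos for a in placed.all_atoms()
                          if a.element in ("N", "O", "S")])
    for other in ctx["helices"]:
        oc = np.array([a.pos for a in other.all_atoms() if not a.is_hydrogen])
        if oc.size and new_coords.size:
            d = np.linalg.norm(new_coords[:, None, :] - oc[None, :, :], axis=2)
            if float(d.min()) < _CLASH:
                return False
        # polar atoms of distinct helices stay out of HB range of each
        # other so a late placement cannot flip an earlier rotamer choice
        op = np.array([a.pos for a in other.all_atoms()
                       if a.element in ("N", "O", "S")])
        if op.size and new_polar.size:
            d = np.linalg.norm(new_polar[:, None, :] - op[None, :, :], axis=2)
            if float(d.min()) < _POLAR_EXCLUSION:
                return False
    return True


def _verify_planted_pocket(model: StructureModel, ligand: LigandInstance,
                           manifest: FixtureManifest, cutoff: float) -> None:
    """Independent all-pairs check that the planted pocket is exact."""
    lig = ligand.coords(heavy_only=True)
    found = set()
    for res in model.iter_protein_residues():
        heavy = np.array([a.pos for a in res.heavy_atoms])
        d = np.linalg.norm(heavy[:, None, :] - lig[None, :, :], axis=2)
        if float(d.min()) <= cutoff:
            found.add((res.name, res.number))
    if found != set(manifest.pocket):
        raise InfeasibleSpecError(
            f"planted pocket verification failed: planted {manifest.pocket}, "
            f"realised {sorted(found)}")


# ---------------------------------------------------------------------------
# perturbations

def perturb(model: StructureModel, mode: str, seed: int = 0,
            sigma: float = 0.0,
            transform: Optional[RigidTransform] = None
            ) -> tuple[StructureModel, FixtureManifest]:
    """Rigidly move a model or add per-atom Gaussian noise.

    In rigid mode the manifest records the applied rotation/translation so
    that Kabsch recovery can be asserted exactly; in noise mode it records
    the realised post-superposition RMSD of the actual noise draw.
    """
    rng = np.random.default_rng(seed)
    out = model.copy()
    manifest = FixtureManifest(seed=seed)
    atoms = out.all_atoms()
    coords = np.array([a.pos for a in atoms])

    if mode == "rigid":
        if transform is None:
            axis = rng.normal(size=3)
            angle = float(rng.uniform(10.0, 170.0))
            rot = rotation_about_axis(axis, angle)
            t = rng.uniform(-10.0, 10.0, size=3)
            transform = RigidTransform(rot, t)
        new = transform.apply(coords)
        manifest.rotation = transform.rotation.tolist()
        manifest.translation = transform.translation.tolist()
    elif mode == "noise":
        if sigma < 0:
            raise ModelError("sigma must be >= 0")
        new = coords + rng.normal(0.0, sigma, size=coords.shape)
        manifest.noise_sigma = sigma
        if len(atoms) >= 3 and sigma >= 0:
            result = kabsch(coords, new)
            manifest.realized_rmsd = result.rmsd
        else:
            manifest.realized_rmsd = 0.0
    else:
        raise ModelError(f"unknown perturbation mode {mode!r}")

    for atom, p in zip(atoms, new):
        atom.pos = p
    return out, manifest
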