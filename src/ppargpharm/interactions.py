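"""Geometric detection of hydrogen bonds, salt bridges and water bridges,
plus activation-helix (H12) contact analysis against an apo reference.

Hydrogen bonds are accepted when the donor-acceptor heavy-atom distance is
at most 3.5 A and, when a donor hydrogen is present, the D-H...A angle is
at least 120 degrees.  These fixed geometric criteria replace trained
probabilistic scores: they are reproducible and tunable via
:class:`HBCriteria`.

Donor/acceptor typing: N/O/S atoms carrying a hydrogen donate; N/O atoms
with a free lone pair accept (carboxylate, carbonyl and hydroxyl oxygens,
non-protonated imidazole nitrogens); thioether sulphur is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import yaml

from .geometry import angle_deg
from .model import Atom, LigandInstance, ModelError, Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "HBCriteria", "HBond", "ContactRecord", "HelixAnnotation",
    "find_hbonds", "find_salt_bridges", "find_water_bridges",
    "helix_contacts", "unique_contacts", "compute_helix_annotation",
    "default_helix_annotation",
]


@dataclass(frozen=True)
class HBCriteria:
    max_distance: float = 3.5   # D...A heavy-atom distance, A
    min_angle: float = 120.0    # D-H...A angle, deg (when H present)


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    resname: str
    resnum: int
    atom_name: str
    is_ligand: bool = False
    is_water: bool = False

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.resname, self.resnum)

    def __str__(self) -> str:
        return f"{self.resname}{self.resnum}:{self.atom_name}"


@dataclass
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    angle: Optional[float]          # None when no donor H is available
    direction: str                  # ligand->protein | protein->ligand | protein->protein
    helix_donor: Optional[str] = None
    helix_acceptor: Optional[str] = None

    @property
    def protein_residue(self) -> tuple[str, int]:
        ref = self.acceptor if self.donor.is_ligand else self.donor
        return ref.residue_key


@dataclass(frozen=True)
class ContactRecord:
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    helix_a: Optional[str]
    helix_b: Optional[str]
    kind: str                       # hbond | salt-bridge | water-bridge
    distance: float = 0.0

    @property
    def key(self) -> tuple:
        pair = tuple(sorted([self.residue_a, self.residue_b],
                            key=lambda r: (r[1], r[0])))
        return (*pair, self.kind)


# ---------------------------------------------------------------------------
# donor / acceptor typing

_ACCEPTOR_ONLY_O = True  # backbone + side-chain oxygens always accept


def _attached_hydrogens(res_atoms: list[Atom], heavy: Atom) -> list[Atom]:
    return [a for a in res_atoms
            if a.is_hydrogen and np.linalg.norm(a.pos - heavy.pos) <= 1.35]


def _protein_polar_atoms(res: Residue) -> list[tuple[Atom, bool, bool, list[Atom]]]:
    """Yield (atom, is_donor, is_acceptor, attached H) for one residue."""
    out = []
    for atom in res.atoms:
        if atom.element not in ("N", "O", "S"):
            continue
        hs = _attached_hydrogens(res.atoms, atom)
        donor = bool(hs)
        if atom.element == "O":
            acceptor = True
        elif atom.element == "N":
            acceptor = not donor           # bare imidazole/azine N accepts
        else:  # S: thiol donates; thioether excluded entirely
            acceptor = False
            if not hs:
                continue
        out.append((atom, donor, acceptor, hs))
    return out


def _ligand_polar_atoms(lig: LigandInstance) -> list[tuple[Atom, bool, bool, list[Atom]]]:
    out = []
    for i, atom in enumerate(lig.atoms):
        if atom.element not in ("N", "O", "S"):
            continue
        hs = _attached_hydrogens(lig.atoms, atom)
        donor = bool(hs)
        if atom.element == "O":
            acceptor = True
        elif atom.element == "N":
            acceptor = (not donor) and lig.charge_of(i) <= 0 \
                and len(lig.neighbors(i) or []) <= 3
        else:
            acceptor = False
            if not hs:
                continue
        out.append((atom, donor, acceptor, hs))
    return out


def _hb_geometry(donor: Atom, donor_hs: list[Atom], acceptor: Atom,
                 criteria: HBCriteria) -> Optional[tuple[float, Optional[float]]]:
    d = float(np.linalg.norm(donor.pos - acceptor.pos))
    if d > criteria.max_distance or d < 0.5:
        return None
    if not donor_hs:
        return d, None
    best = max(angle_deg(donor.pos, h.pos, acceptor.pos) for h in donor_hs)
    if best < criteria.min_angle:
        return None
    return d, best


# ---------------------------------------------------------------------------
# helix annotation

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class HelixAnnotation:
    """Secondary-structure ranges (inclusive author numbers) plus the
    activation-helix vicinity used for contact analysis."""

    ranges: dict[str, tuple[int, int]]
    vicinity: tuple[int, int]       # linker before H12 through chain end
    h12: str = "H12"

    def __post_init__(self) -> None:
        spans = sorted(self.ranges.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ModelError("helix ranges overlap")

    def label(self, resnum: int) -> str:
        for name, (lo, hi) in self.ranges.items():
            if lo <= resnum <= hi:
                return name
        h12_hi = self.ranges.get(self.h12, (0, 0))[1]
        if resnum > h12_hi and self.vicinity[0] <= resnum <= self.vicinity[1]:
            return "after H12"
        if self.vicinity[0] <= resnum <= self.vicinity[1]:
            return "H10/11-H12 linker"
        return "loop"

    def in_focus(self, resnum: int) -> bool:
        """True in H12 or its vicinity (linker through chain terminus)."""
        lo, hi = self.vicinity
        h12 = self.ranges.get(self.h12)
        return (lo <= resnum <= hi) or (h12 and h12[0] <= resnum <= h12[1])

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "HelixAnnotation":
        data = yaml.safe_load(Path(path).read_text())
        ranges = {k: tuple(v) for k, v in data["ranges"].items()}
        ann = cls(ranges=ranges, vicinity=tuple(data["vicinity"]),
                  h12=data.get("h12", "H12"))
        for anchor in data.get("anchors", []):
            expected, resnum = anchor["label"], int(anchor["resnum"])
            got = ann.label(resnum)
            if got != expected:
                if anchor.get("strict", True):
                    raise ModelError(
                        f"helix annotation anchor failed: residue {resnum} "
                        f"labelled {got!r}, expected {expected!r}")
                logger.warning("annotation anchor: residue %d is %r here, "
                               "%r elsewhere in the literature",
                               resnum, got, expected)
        return ann


def default_helix_annotation() -> HelixAnnotation:
    """The shipped annotation for the receptor 206-477 numbering."""
    return HelixAnnotation.from_yaml(_DATA_DIR / "helices_pparg.yaml")


def compute_helix_annotation(model: StructureModel,
                             chain_id: Optional[str] = None,
                             min_length: int = 5) -> HelixAnnotation:
    """Assign helix ranges from backbone hydrogen-bond patterns (DSSP via
    mdtraj) and number the helical segments sequentially."""
    import tempfile

    import mdtraj

    from . import structure_io

    sub = model.copy()
    if chain_id is not None:
        sub.chains = [c for c in sub.chains if c.chain_id == chain_id]
    sub.het_groups, sub.waters = [], []
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(structure_io.write_pdb(sub))
        path = fh.name
    traj = mdtraj.load(path)
    ss = mdtraj.compute_dssp(traj, simplified=True)[0]
    numbers = [r.number for r in sub.iter_protein_residues()]
    ranges: dict[str, tuple[int, int]] = {}
    idx = 0
    start = None
    for i, code in enumerate(ss):
        if code == "H" and start is None:
            start = i
        if (code != "H" or i == len(ss) - 1) and start is not None:
            end = i if code == "H" else i - 1
            if end - start + 1 >= min_length:
                idx += 1
                ranges[f"H{idx}"] = (numbers[start], numbers[end])
            start = None
    if not ranges:
        raise ModelError("no helical segments found")
    last = max(ranges, key=lambda k: ranges[k][1])
    vicinity = (ranges[last][0] - 5, numbers[-1])
    return HelixAnnotation(ranges=ranges, vicinity=vicinity, h12=last)


# ---------------------------------------------------------------------------
# detection

def find_hbonds(model: StructureModel, ligand: LigandInstance,
                criteria: HBCriteria = HBCriteria(),
                helix_annotation: Optional[HelixAnnotation] = None
                ) -> list[HBond]:
    """All ligand-protein hydrogen bonds under the geometric criteria."""
    lig_polar = _ligand_polar_atoms(ligand)
    if not lig_polar:
        return []
    out: list[HBond] = []
    for res in model.iter_protein_residues():
        for p_atom, p_don, p_acc, p_hs in _protein_polar_atoms(res):
            for l_atom, l_don, l_acc, l_hs in lig_polar:
                p_ref = AtomRef(res.chain_id, res.name, res.number, p_atom.name)
                l_ref = AtomRef(ligand.chain_id, ligand.comp_id,
                                ligand.residue_number, l_atom.name,
                                is_ligand=True)
                if l_don and p_acc:
                    geom = _hb_geometry(l_atom, l_hs, p_atom, criteria)
                    if geom:
                        out.append(_mk_hbond(l_ref, p_ref, geom,
                                             "ligand->protein",
                                             helix_annotation))
                if p_don and l_acc:
                    geom = _hb_geometry(p_atom, p_hs, l_atom, criteria)
                    if geom:
                        out.append(_mk_hbond(p_ref, l_ref, geom,
                                             "protein->ligand",
                                             helix_annotation))
    return out


def _mk_hbond(donor: AtomRef, acceptor: AtomRef, geom, direction,
              annotation: Optional[HelixAnnotation]) -> HBond:
    d, ang = geom
    hb = HBond(donor, acceptor, round(d, 4),
               None if ang is None else round(ang, 2), direction)
    if annotation is not None:
        if not donor.is_ligand:
            hb.helix_donor = annotation.label(donor.resnum)
        if not acceptor.is_ligand:
            hb.helix_acceptor = annotation.label(acceptor.resnum)
    return hb


_POSITIVE_PROTEIN = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
_NEGATIVE_PROTEIN = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def find_salt_bridges(model: StructureModel, ligand: LigandInstance,
                      cutoff: float = 4.0,
                      helix_annotation: Optional[HelixAnnotation] = None
                      ) -> list[ContactRecord]:
    """Oppositely charged ligand/protein N/O heavy-atom pairs within 4.0 A."""
    lig_charged = [(a, ligand.charge_of(i)) for i, a in enumerate(ligand.atoms)
                   if ligand.charge_of(i) and a.element in ("N", "O")]
    if not lig_charged:
        return []
    out = []
    for res in model.iter_protein_residues():
        for names, sign in ((_POSITIVE_PROTEIN.get(res.name, ()), +1),
                            (_NEGATIVE_PROTEIN.get(res.name, ()), -1)):
            for nm in names:
                p_atom = res.atom(nm)
                if p_atom is None:
                    continue
                for l_atom, q in lig_charged:
                    if q * sign >= 0:
                        continue
                    d = float(np.linalg.norm(p_atom.pos - l_atom.pos))
                    if d <= cutoff:
                        ann = helix_annotation
                        out.append(ContactRecord(
                            (res.name, res.number),
                            (ligand.comp_id, ligand.residue_number),
                            ann.label(res.number) if ann else None, None,
                            "salt-bridge", round(d, 4)))
    return out


def find_water_bridges(model: StructureModel, ligand: LigandInstance,
                       criteria: HBCriteria = HBCriteria()
                       ) -> list[tuple[AtomRef, AtomRef, AtomRef]]:
    """Waters hydrogen-bonding the ligand and a protein residue at once.

    Water hydrogens are not modelled, so water-involved contacts are
    accepted on the distance criterion alone (the angle term applies only
    when a donor hydrogen exists).
    """
    out = []
    lig_polar = _ligand_polar_atoms(ligand)
    protein_polar = [(res, tup) for res in model.iter_protein_residues()
                     for tup in _protein_polar_atoms(res)]
    for water in model.waters:
        w_atom = water.atom("O") or (water.atoms[0] if water.atoms else None)
        if w_atom is None:
            continue
        lig_hits = [a for a, don, acc, _hs in lig_polar
                    if (don or acc)
                    and np.linalg.norm(a.pos - w_atom.pos) <= criteria.max_distance]
        if not lig_hits:
            continue
        prot_hits = [(res, a) for res, (a, don, acc, _hs) in protein_polar
                     if (don or acc)
                     and np.linalg.norm(a.pos - w_atom.pos) <= criteria.max_distance]
        w_ref = AtomRef(water.chain_id, "HOH", water.number, w_atom.name,
                        is_water=True)
        for l_atom in lig_hits:
            for res, p_atom in prot_hits:
                out.append((
                    AtomRef(ligand.chain_id, ligand.comp_id,
                            ligand.residue_number, l_atom.name, is_ligand=True),
                    w_ref,
                    AtomRef(res.chain_id, res.name, res.number, p_atom.name),
                ))
    return out


def helix_contacts(model: StructureModel, annotation: HelixAnnotation,
                   criteria: HBCriteria = HBCriteria()) -> list[ContactRecord]:
    """Protein-protein hydrogen bonds with exactly one partner in the
    activation-helix focus region (H12 and its vicinity).

    Backbone-neighbour pairs (|residue number difference| <= 2) are
    excluded so that the intrinsic helical i,i+4 pattern inside H12 does
    not read as a stabilising contact; contacts are keyed by residue pair.
    """
    residues = list(model.iter_protein_residues())
    focus = [r for r in residues if annotation.in_focus(r.number)]
    if not focus:
        raise ModelError("helix-annotation focus region is empty for this model")
    polar = [(res, tup) for res in residues for tup in _protein_polar_atoms(res)]
    seen: dict[tuple, ContactRecord] = {}
    for res_a, (atom_a, don_a, acc_a, hs_a) in polar:
        for res_b, (atom_b, don_b, acc_b, hs_b) in polar:
            if res_a is res_b:
                continue
            if abs(res_a.number - res_b.number) <= 2 \
                    and res_a.chain_id == res_b.chain_id:
                continue
            a_in = annotation.in_focus(res_a.number)
            b_in = annotation.in_focus(res_b.number)
            if a_in == b_in:
                continue
            if not (don_a and acc_b):
                continue
            geom = _hb_geometry(atom_a, hs_a, atom_b, criteria)
            if geom is None:
                continue
            rec = ContactRecord(
                (res_a.name, res_a.number), (res_b.name, res_b.number),
                annotation.label(res_a.number), annotation.label(res_b.number),
                "hbond", round(geom[0], 4))
            seen.setdefault(rec.key, rec)
    return sorted(seen.values(), key=lambda r: r.key)


def unique_contacts(holo_records: Iterable[ContactRecord],
                    apo_records: Iterable[ContactRecord]
                    ) -> list[ContactRecord]:
    """Contacts present in the holo analysis and absent from the apo one,
    keyed by residue pair and interaction type."""
    apo_keys = {r.key for r in apo_records}
    out, seen = [], set()
    for rec in holo_records:
        if rec.key not in apo_keys and rec.key not in seen:
            seen.add(rec.key)
            out.append(rec)
    return out
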