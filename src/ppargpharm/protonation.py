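"""Rule-based ionisation assignment and polar-hydrogen placement at pH 7.4.

Side-chain pKa rules at physiological pH: Asp/Glu deprotonated, Lys/Arg
protonated, Cys/Tyr/Ser/Thr neutral.  Histidine tautomers are chosen by
counting satisfiable hydrogen bonds to neighbouring polar atoms within
3.5 A (default N-epsilon-H when nothing decides).  Hydroxyl/thiol rotamers
are enumerated over the three staggered torsions and the one making the
most hydrogen bonds wins, ties broken by the numerically lowest torsion.

Only the pH 7.4 rule table ships; other pH values raise NotImplementedError
rather than silently misassigning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import place_atom, unit
from .model import Atom, LigandInstance, ModelError, Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = ["ProtonationAssignment", "assign_ionization", "place_polar_hydrogens"]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split())

RESIDUE_CHARGES = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}

#: allowed per-residue states
STATES = ("default", "deprotonated-acid", "protonated-base",
          "HIS-Nd", "HIS-Ne", "HIS-protonated")

_ROTAMER_TORSIONS = (-60.0, 60.0, 180.0)  # enumeration; tie -> lowest value

#: protein acceptor atoms by residue (backbone O handled separately)
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
}
#: protein donor heavy atoms by residue (backbone N handled separately)
_SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",),
    "GLN": ("NE2",), "TRP": ("NE1",),
}


@dataclass
class ProtonationAssignment:
    """Ionisation states per residue plus per-ligand formal charges."""

    residue_states: dict[tuple[str, int, str], str] = field(default_factory=dict)
    residue_charges: dict[tuple[str, int, str], int] = field(default_factory=dict)
    ligand_charges: dict[tuple[str, str, int], int] = field(default_factory=dict)
    ph: float = 7.4

    @property
    def net_charge(self) -> int:
        return sum(self.residue_charges.values()) + sum(self.ligand_charges.values())

    def state_of(self, res: Residue) -> str:
        return self.residue_states.get((res.chain_id, res.number, res.icode),
                                       "default")


def _polar_environment(model: StructureModel
                       ) -> list[tuple[np.ndarray, str, tuple]]:
    """All polar heavy atoms with a crude donor/acceptor/both tag and the
    identity of the residue (or het group) that owns them, so that
    intra-residue contacts can be excluded from hydrogen-bond counting."""
    env: list[tuple[np.ndarray, str, tuple]] = []
    for res in model.iter_protein_residues():
        key = ("res", res.chain_id, res.number, res.icode)
        for a in res.atoms:
            if a.name == "O":
                env.append((a.pos, "acceptor", key))
            elif a.name == "N":
                env.append((a.pos, "donor", key))
        for nm in _SIDECHAIN_ACCEPTORS.get(res.name, ()):
            at = res.atom(nm)
            if at is not None:
                tag = "both" if res.name in ("SER", "THR", "TYR") else "acceptor"
                env.append((at.pos, tag, key))
        for nm in _SIDECHAIN_DONORS.get(res.name, ()):
            at = res.atom(nm)
            if at is not None and res.name not in ("SER", "THR", "TYR"):
                env.append((at.pos, "donor", key))
    for w in model.waters:
        o = w.atom("O") or (w.atoms[0] if w.atoms else None)
        if o is not None:
            env.append((o.pos, "both", ("wat", w.chain_id, w.number)))
    for lig in model.het_groups:
        lkey = ("het", lig.comp_id, lig.chain_id, lig.residue_number)
        for a in lig.heavy_atoms:
            if a.element in ("N", "O"):
                env.append((a.pos, "both", lkey))
    return env


def _his_tautomer(res: Residue, env) -> str:
    """Pick HIS-Nd or HIS-Ne by satisfied-HB count within 2.5-3.5 A,
    ignoring atoms of the histidine itself."""
    nd1, ne2 = res.atom("ND1"), res.atom("NE2")
    if nd1 is None or ne2 is None:
        return "HIS-Ne"
    own = ("res", res.chain_id, res.number, res.icode)

    def satisfied(protonated: Atom, bare: Atom) -> int:
        count = 0
        for pos, tag, key in env:
            if key == own:
                continue
            d_p = float(np.linalg.norm(pos - protonated.pos))
            d_b = float(np.linalg.norm(pos - bare.pos))
            if 2.5 <= d_p <= 3.5 and tag in ("acceptor", "both"):
                count += 1
            if 2.5 <= d_b <= 3.5 and tag in ("donor", "both"):
                count += 1
        return count

    n_delta = satisfied(nd1, ne2)
    n_eps = satisfied(ne2, nd1)
    if n_delta > n_eps:
        return "HIS-Nd"
    return "HIS-Ne"


def assign_ionization(model: StructureModel, ph: float = 7.4,
                      ligand_overrides: Optional[dict[str, int]] = None
                      ) -> ProtonationAssignment:
    """Assign side-chain and ligand ionisation states at physiological pH.

    ``ligand_overrides`` maps component ids to net formal charges that
    replace the rule-based ligand assignment.
    """
    if abs(ph - 7.4) > 1e-9:
        raise NotImplementedError(
            "only the pH 7.4 rule table is implemented; refusing to guess "
            f"states at pH {ph}")
    assignment = ProtonationAssignment(ph=ph)
    env = _polar_environment(model)
    for res in model.iter_protein_residues():
        key = (res.chain_id, res.number, res.icode)
        if res.name not in STANDARD_RESIDUES:
            logger.warning("non-standard residue %s: state left default",
                           res.label)
            assignment.residue_states[key] = "default"
            continue
        if res.name in ("ASP", "GLU"):
            assignment.residue_states[key] = "deprotonated-acid"
            assignment.residue_charges[key] = -1
        elif res.name in ("LYS", "ARG"):
            assignment.residue_states[key] = "protonated-base"
            assignment.residue_charges[key] = +1
        elif res.name == "HIS":
            state = _his_tautomer(res, env)
            assignment.residue_states[key] = state
            logger.info("His%s tautomer: %s", res.number, state)
        else:
            assignment.residue_states[key] = "default"

    overrides = ligand_overrides or {}
    for lig in model.het_groups:
        key = (lig.comp_id, lig.chain_id, lig.residue_number)
        if lig.comp_id in overrides:
            assignment.ligand_charges[key] = overrides[lig.comp_id]
            continue
        assignment.ligand_charges[key] = _ligand_rule_charge(lig)
    return assignment


def _ligand_rule_charge(lig: LigandInstance) -> int:
    """Carboxylic acids deprotonated (-1 each), aliphatic amines protonated
    (+1 each); thiazolidinedione-type ring N-H stays neutral."""
    if not lig.bonds:
        return lig.net_charge
    charge = 0
    for i, atom in enumerate(lig.atoms):
        if lig.charge_of(i):
            charge += lig.charge_of(i)
            continue
        nbrs = lig.neighbors(i)
        if atom.element == "C":
            terminal_o = [j for j in nbrs
                          if lig.atoms[j].element == "O"
                          and len(lig.neighbors(j)) == 1]
            if len(terminal_o) == 2 and not any(
                    lig.charge_of(j) for j in terminal_o):
                charge -= 1
        elif atom.element == "N":
            heavy = [j for j in nbrs if not lig.atoms[j].is_hydrogen]
            carbonyl_neighbor = any(
                lig.atoms[j].element == "C" and any(
                    lig.atoms[k].element == "O"
                    and (lig.bond_between(j, k) or (0, 0, 1, False))[2] == 2
                    for k in lig.neighbors(j))
                for j in heavy)
            aromatic = any(b[3] for b in lig.bonds if i in b[:2])
            if (not carbonyl_neighbor and not aromatic and len(heavy) <= 3
                    and all(lig.atoms[j].element == "C" for j in heavy)
                    and heavy):
                charge += 1
    return charge


# ---------------------------------------------------------------------------
# hydrogen placement

_OH_GROUPS = {  # residue -> (H name, heavy, anchor, frame atom, bond length)
    "SER": ("HG", "OG", "CB", "CA", 0.96),
    "THR": ("HG1", "OG1", "CB", "CA", 0.96),
    "TYR": ("HH", "OH", "CZ", "CE1", 0.96),
    "CYS": ("HG", "SG", "CB", "CA", 1.34),
}


def _count_hbonds_for_h(h_pos: np.ndarray, donor_pos: np.ndarray,
                        acceptors: list[np.ndarray]) -> int:
    """Hydrogen bonds a placed H would satisfy: D...A within 2.5-3.5 A and
    D-H...A of at least 120 degrees (the 2.5 A floor skips covalently
    adjacent atoms of the same residue)."""
    from .geometry import angle_deg

    count = 0
    for apos in acceptors:
        d = float(np.linalg.norm(apos - donor_pos))
        if not 2.5 <= d <= 3.5:
            continue
        if angle_deg(donor_pos, h_pos, apos) >= 120.0:
            count += 1
    return count


def place_polar_hydrogens(model: StructureModel,
                          assignment: ProtonationAssignment) -> StructureModel:
    """Place O-H, N-H and S-H hydrogens consistent with an assignment.

    Rotatable hydroxyl/thiol torsions are chosen from the staggered set
    {-60, 60, 180} by maximising hydrogen bonds to neighbouring acceptors;
    ties go to the numerically lowest torsion.  Re-running removes and
    re-places previously placed hydrogens, so the operation is idempotent.
    """
    out = model.copy()
    # idempotence: strip hydrogens placed by an earlier run
    for res in list(out.iter_protein_residues()) + out.waters:
        res.atoms = [a for a in res.atoms if not a.placed]
    for lig in out.het_groups:
        keep = [k for k, a in enumerate(lig.atoms) if not a.placed]
        remap = {old: new for new, old in enumerate(keep)}
        lig.bonds = [(remap[i], remap[j], o, ar) for (i, j, o, ar) in lig.bonds
                     if i in remap and j in remap]
        lig.formal_charges = {remap[i]: q for i, q in lig.formal_charges.items()
                              if i in remap}
        lig.atoms = [lig.atoms[k] for k in keep]

    environment = [(pos, key) for pos, tag, key in _polar_environment(out)
                   if tag in ("acceptor", "both")]

    for chain in out.chains:
        prev_c: Optional[Atom] = None
        for res in chain.residues:
            _place_backbone_nh(res, prev_c)
            own = ("res", res.chain_id, res.number, res.icode)
            acceptors = [pos for pos, key in environment if key != own]
            _place_sidechain_h(res, assignment, acceptors)
            prev_c = res.atom("C")
    for lig in out.het_groups:
        _place_ligand_h(lig, assignment)
    return out


def _add_h(res: Residue, name: str, pos: np.ndarray) -> None:
    if res.atom(name) is not None:
        return  # hydrogen already present in the input
    res.atoms.append(Atom(name, "H", pos, placed=True))


def _place_backbone_nh(res: Residue, prev_c: Optional[Atom]) -> None:
    if res.name == "PRO":
        return
    n, ca = res.atom("N"), res.atom("CA")
    if n is None or ca is None or prev_c is None:
        return  # chain start or missing anchor
    # H anti to the bisector of C(prev)-N-CA, in the peptide plane
    direction = -unit(unit(prev_c.pos - n.pos) + unit(ca.pos - n.pos))
    _add_h(res, "H", n.pos + 1.01 * direction)


def _place_sidechain_h(res: Residue, assignment: ProtonationAssignment,
                       acceptors: list[np.ndarray]) -> None:
    name = res.name
    state = assignment.state_of(res)

    if name in _OH_GROUPS:
        h_name, heavy_nm, anchor_nm, frame_nm, bond = _OH_GROUPS[name]
        heavy, anchor, frame = (res.atom(heavy_nm), res.atom(anchor_nm),
                                res.atom(frame_nm))
        if heavy is None or anchor is None or frame is None:
            logger.warning("%s: missing anchor for %s-H, skipped",
                           res.label, heavy_nm)
            return
        best = None
        for torsion in sorted(_ROTAMER_TORSIONS):
            pos = place_atom(frame.pos, anchor.pos, heavy.pos,
                             bond, 109.5, torsion)
            n_hb = _count_hbonds_for_h(pos, heavy.pos, acceptors)
            if best is None or n_hb > best[0]:
                best = (n_hb, torsion, pos)
        _add_h(res, h_name, best[2])

    elif name == "LYS" and state == "protonated-base":
        nz, ce, cd = res.atom("NZ"), res.atom("CE"), res.atom("CD")
        if nz is None or ce is None or cd is None:
            logger.warning("%s: missing NZ anchors, skipped", res.label)
            return
        for k, torsion in enumerate((60.0, 180.0, -60.0)):
            _add_h(res, f"HZ{k+1}",
                   place_atom(cd.pos, ce.pos, nz.pos, 1.01, 109.5, torsion))

    elif name == "ARG" and state == "protonated-base":
        cz, ne, cd = res.atom("CZ"), res.atom("NE"), res.atom("CD")
        nh1, nh2 = res.atom("NH1"), res.atom("NH2")
        if None in (cz, ne, cd, nh1, nh2):
            logger.warning("%s: missing guanidinium atoms, skipped", res.label)
            return
        _add_h(res, "HE", place_atom(cd.pos, cz.pos, ne.pos, 1.01, 119.0, 180.0))
        for nh, labels in ((nh1, ("HH11", "HH12")), (nh2, ("HH21", "HH22"))):
            for lbl, tor in zip(labels, (0.0, 180.0)):
                _add_h(res, lbl, place_atom(ne.pos, cz.pos, nh.pos,
                                            1.01, 120.0, tor))

    elif name == "HIS":
        cg, nd1, ce1, ne2, cd2 = (res.atom(a) for a in
                                  ("CG", "ND1", "CE1", "NE2", "CD2"))
        if None in (cg, nd1, ce1, ne2, cd2):
            return
        if state in ("HIS-Nd", "HIS-protonated"):
            # in-plane H on ND1, exterior bisector of CG-ND1-CE1
            direction = -unit(unit(cg.pos - nd1.pos) + unit(ce1.pos - nd1.pos))
            _add_h(res, "HD1", nd1.pos + 1.01 * direction)
        if state in ("HIS-Ne", "HIS-protonated", "default"):
            direction = -unit(unit(cd2.pos - ne2.pos) + unit(ce1.pos - ne2.pos))
            _add_h(res, "HE2", ne2.pos + 1.01 * direction)

    elif name in ("ASN", "GLN"):
        if name == "ASN":
            nN, cC, oO = res.atom("ND2"), res.atom("CG"), res.atom("OD1")
            labels = ("HD21", "HD22")
        else:
            nN, cC, oO = res.atom("NE2"), res.atom("CD"), res.atom("OE1")
            labels = ("HE21", "HE22")
        if None in (nN, cC, oO):
            return
        for lbl, tor in zip(labels, (0.0, 180.0)):
            _add_h(res, lbl, place_atom(oO.pos, cC.pos, nN.pos, 1.01, 120.0, tor))

    elif name == "TRP":
        ne1, cd1, ce2 = res.atom("NE1"), res.atom("CD1"), res.atom("CE2")
        if None in (ne1, cd1, ce2):
            return
        direction = -unit(unit(cd1.pos - ne1.pos) + unit(ce2.pos - ne1.pos))
        _add_h(res, "HE1", ne1.pos + 1.01 * direction)


def _place_ligand_h(lig: LigandInstance, assignment: ProtonationAssignment
                    ) -> None:
    """Minimal valence-rule hydrogen placement for het groups.

    Covers the chemistry the annotation module needs: hydroxyl O-H,
    secondary amide / ring N-H, and protonated amine N-H3.  Atoms already
    carrying hydrogens are left alone.
    """
    if not lig.bonds:
        return
    n0 = len(lig.atoms)
    for i in range(n0):
        atom = lig.atoms[i]
        if atom.is_hydrogen:
            continue
        nbrs = lig.neighbors(i)
        h_nbrs = [j for j in nbrs if lig.atoms[j].is_hydrogen]
        heavy = [j for j in nbrs if not lig.atoms[j].is_hydrogen]
        charge = lig.charge_of(i)
        want = 0
        if atom.element == "O" and charge == 0 and len(heavy) == 1 and not h_nbrs:
            bond = lig.bond_between(i, heavy[0])
            if bond and bond[2] == 1:
                # carboxylic O stays bare (acid deprotonated by rule)
                partner = heavy[0]
                partner_term_o = [k for k in lig.neighbors(partner)
                                  if lig.atoms[k].element == "O"
                                  and len(lig.neighbors(k)) == 1]
                if len(partner_term_o) < 2:
                    want = 1
        elif atom.element == "N":
            aromatic = any(b[3] for b in lig.bonds if i in b[:2])
            if charge == 1:
                want = max(0, 4 - len(heavy) - len(h_nbrs))
            elif not aromatic and len(heavy) == 2 and not h_nbrs:
                want = 1
        for k in range(want):
            direction = -unit(np.sum(
                [unit(lig.atoms[j].pos - atom.pos) for j in nbrs], axis=0))
            if want > 1:
                jitter = np.array([0.4 * (k - (want - 1) / 2), 0.25 * k, 0.3])
                direction = unit(direction + jitter)
            bond_len = 1.01 if atom.element == "N" else 0.96
            idx = len(lig.atoms)
            lig.atoms.append(Atom(f"H{atom.name}"[:3] + str(k + 1), "H",
                                  atom.pos + bond_len * direction, placed=True))
            lig.bonds.append((i, idx, 1, False))
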