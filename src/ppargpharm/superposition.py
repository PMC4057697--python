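"""Rigid-body superposition (Kabsch), RMSD on selections, template overlays
and force-field relaxation of ligands.

The optimal proper rotation is obtained from the SVD of the covariance
matrix of the centred point sets, with the standard reflection guard
(sign flip of the smallest singular vector when the determinant of the
candidate rotation is negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import Chain, LigandInstance, ModelError, Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform", "SuperpositionResult", "kabsch", "pair_calpha",
    "superpose_all", "transform_model", "rmsd_on_selection", "relax_ligand",
    "ligand_cross_complex_rmsd", "rmsd_histogram", "detect_receptor_chain",
]


@dataclass
class RigidTransform:
    """x -> R @ x + t, rotation proper orthogonal."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ModelError("rigid transform must be 3x3 rotation + 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ModelError("rotation matrix is not orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ModelError("rotation matrix is a reflection (det < 0)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    pairing: Optional[list[tuple]] = None


def kabsch(fixed: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of mobile onto fixed.

    Returns the transform together with the RMSD after applying it.
    Requires >= 3 non-collinear point pairs.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape:
        raise ModelError(
            f"point set length mismatch: {fixed.shape} vs {mobile.shape}")
    if fixed.ndim != 2 or fixed.shape[1] != 3 or fixed.shape[0] < 3:
        raise ModelError("superposition needs >= 3 paired 3D points")
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    x = fixed - cf
    y = mobile - cm
    if min(np.linalg.matrix_rank(x, tol=1e-8),
           np.linalg.matrix_rank(y, tol=1e-8)) < 2:
        raise ModelError("degenerate (collinear) point set")
    h = y.T @ x
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cf - rot @ cm
    transform = RigidTransform(rot, t)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return SuperpositionResult(transform, rmsd, fixed.shape[0])


def pair_calpha(template_chain: Chain, target_chain: Chain
                ) -> tuple[np.ndarray, np.ndarray, list[tuple[Residue, Residue]]]:
    """Pair C-alpha atoms of two chains by author residue number.

    Residues are paired when numbers (and insertion codes) coincide; when
    both residue names are present and differ, the pair is dropped and
    logged.  Returns (template coords, target coords, pairing).
    """
    target_index = {(r.number, r.icode): r for r in target_chain.residues
                    if r.atom("CA") is not None}
    fixed, mobile, pairing = [], [], []
    for res in template_chain.residues:
        ca = res.atom("CA")
        if ca is None:
            continue
        other = target_index.get((res.number, res.icode))
        if other is None:
            continue
        if res.name and other.name and res.name != other.name:
            logger.info("dropping pair %s/%s: residue name mismatch %s vs %s",
                        res.number, res.icode, res.name, other.name)
            continue
        fixed.append(ca.pos)
        mobile.append(other.atom("CA").pos)
        pairing.append((res, other))
    if len(pairing) < 3:
        raise ModelError(
            f"only {len(pairing)} C-alpha pairs between chains "
            f"{template_chain.chain_id} and {target_chain.chain_id}")
    return np.array(fixed), np.array(mobile), pairing


def detect_receptor_chain(model: StructureModel, template_chain: Chain) -> Chain:
    """Pick the chain with the best residue-number overlap with the template."""
    template_numbers = {r.number for r in template_chain.residues}
    best, best_overlap = None, -1
    for chain in model.chains:
        overlap = sum(1 for r in chain.residues if r.number in template_numbers)
        if overlap > best_overlap:
            best, best_overlap = chain, overlap
    if best is None or best_overlap < 3:
        raise ModelError(f"no chain of {model.entry_id} overlaps the template")
    return best


def transform_model(model: StructureModel, transform: RigidTransform
                    ) -> StructureModel:
    """Apply a rigid transform to every atom (protein, het groups, waters)."""
    out = model.copy()
    for atom in out.all_atoms():
        atom.pos = transform.apply(atom.pos[None, :])[0]
    return out


def superpose_all(
    template_chain: Chain,
    complexes: Iterable[StructureModel],
    chain_overrides: Optional[dict[str, str]] = None,
) -> tuple[pd.DataFrame, dict[str, StructureModel]]:
    """Superpose every complex onto the template chain by C-alpha atoms.

    Returns the RMSD table (accession, chain, n_pairs, rmsd_A) and the
    rigidly transformed models keyed by accession.  Failures to identify a
    receptor chain are reported as rows with NaN rmsd, not raised.
    """
    chain_overrides = chain_overrides or {}
    rows = []
    transformed: dict[str, StructureModel] = {}
    for model in complexes:
        acc = model.entry_id or f"entry{len(rows)}"
        try:
            if acc in chain_overrides:
                chain = model.chain(chain_overrides[acc])
                if chain is None:
                    raise ModelError(f"override chain {chain_overrides[acc]!r} "
                                     f"absent from {acc}")
            else:
                chain = detect_receptor_chain(model, template_chain)
            fixed, mobile, pairing = pair_calpha(template_chain, chain)
            result = kabsch(fixed, mobile)
            transformed[acc] = transform_model(model, result.transform)
            rows.append({"accession": acc, "chain": chain.chain_id,
                         "n_pairs": result.n_pairs,
                         "rmsd_A": round(result.rmsd, 4)})
        except ModelError as exc:
            logger.warning("superposition failed for %s: %s", acc, exc)
            rows.append({"accession": acc, "chain": "", "n_pairs": 0,
                         "rmsd_A": float("nan")})
    return pd.DataFrame(rows), transformed


def rmsd_histogram(rmsd_values: Sequence[float], bin_width: float = 0.2
                   ) -> pd.DataFrame:
    """Histogram of superposition RMSDs with fixed-width bins from 0."""
    values = np.asarray([v for v in rmsd_values if np.isfinite(v)])
    if values.size == 0:
        return pd.DataFrame(columns=["bin_low", "bin_high", "count"])
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame({
        "bin_low": np.round(edges[:-1], 6),
        "bin_high": np.round(edges[1:], 6),
        "count": counts,
    })


Selection = Union[str, Sequence[str]]


def _select_names(ligand: LigandInstance, selection: Selection) -> list[str]:
    if isinstance(selection, str):
        if selection == "all-heavy":
            return [a.name for a in ligand.heavy_atoms]
        if selection == "heteroatoms":
            return [a.name for a in ligand.heavy_atoms
                    if a.element not in ("C", "H")]
        raise ModelError(f"unknown selection {selection!r}")
    return list(selection)


def rmsd_on_selection(a: LigandInstance, b: LigandInstance,
                      selection: Selection = "all-heavy",
                      superpose: bool = True
                      ) -> tuple[float, dict[str, float]]:
    """RMSD between two copies of one ligand on a named atom selection.

    The superposition is performed on the selection itself; per-atom
    distances after superposition are returned keyed by atom name.  With
    ``superpose=False`` coordinates are compared in place.
    """
    names = _select_names(a, selection)
    if not names:
        raise ModelError("empty selection")
    pa, pb = [], []
    for name in names:
        at_a, at_b = a.atom(name), b.atom(name)
        if at_a is None or at_b is None:
            raise ModelError(f"atom {name!r} missing from one of the ligands")
        pa.append(at_a.pos)
        pb.append(at_b.pos)
    pa, pb = np.array(pa), np.array(pb)
    if superpose and len(names) >= 3:
        result = kabsch(pa, pb)
        moved = result.transform.apply(pb)
    else:
        moved = pb
    dists = np.linalg.norm(moved - pa, axis=1)
    rmsd = float(np.sqrt(np.mean(dists ** 2)))
    return rmsd, dict(zip(names, (float(x) for x in dists)))


def _to_rdkit(ligand: LigandInstance):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for i, atom in enumerate(ligand.atoms):
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(ligand.charge_of(i))
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE}
    for i, j, order, aromatic in ligand.bonds:
        mol.AddBond(i, j, Chem.BondType.AROMATIC if aromatic
                    else order_map.get(order, Chem.BondType.SINGLE))
        if aromatic:
            mol.GetAtomWithIdx(i).SetIsAromatic(True)
            mol.GetAtomWithIdx(j).SetIsAromatic(True)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, atom in enumerate(ligand.atoms):
        conf.SetAtomPosition(i, Point3D(*atom.pos))
    mol.AddConformer(conf)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return m


def relax_ligand(ligand: LigandInstance, max_steps: int = 2000,
                 force_tol: float = 1e-4) -> LigandInstance:
    """Energy-minimise a ligand with MMFF94s from its crystallographic pose.

    No conformer search is performed: the minimisation starts from the
    input geometry, so the result is the locally relaxed bioactive
    conformation.  Bonds and formal charges must have been perceived.
    """
    from rdkit.Chem import AllChem

    if not ligand.bonds:
        raise ModelError("relax_ligand requires perceived bonds")
    try:
        mol = _to_rdkit(ligand)
    except Exception as exc:  # rdkit raises bare Exceptions on sanitize
        raise ModelError(f"RDKit could not build {ligand.comp_id}: {exc}") from exc
    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94s")
    if props is None:
        raise ModelError(
            f"MMFF94s atom typing failed for {ligand.comp_id}; atoms: "
            + ",".join(a.name for a in ligand.atoms))
    ff = AllChem.MMFFGetMoleculeForceField(mol, props)
    ff.Minimize(maxIts=max_steps, forceTol=force_tol)
    out = ligand.copy()
    conf = mol.GetConformer()
    for i, atom in enumerate(out.atoms):
        p = conf.GetAtomPosition(i)
        atom.pos = np.array([p.x, p.y, p.z])
    return out


def ligand_cross_complex_rmsd(
    comp_id: str,
    complexes: dict[str, LigandInstance],
    template_ligand: LigandInstance,
    selection: Selection = "all-heavy",
) -> pd.DataFrame:
    """Heavy-atom RMSD of each bound copy of a component vs a template copy.

    Rows with a missing instance are marked absent rather than dropped.
    """
    rows = []
    for acc, lig in complexes.items():
        if lig is None:
            rows.append({"accession": acc, "comp_id": comp_id,
                         "rmsd_A": float("nan"), "absent": True})
            continue
        rmsd, _ = rmsd_on_selection(template_ligand, lig, selection)
        rows.append({"accession": acc, "comp_id": comp_id,
                     "rmsd_A": round(rmsd, 4), "absent": False})
    return pd.DataFrame(rows)
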