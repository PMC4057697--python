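"""Binding-site residue enumeration and cross-complex occurrence statistics.

A pocket residue is a protein residue with at least one heavy atom within a
distance cutoff (default 4.5 A) of at least one ligand heavy atom; waters
are excluded.  X-ray entries lack hydrogens, so cutoff tests use heavy
atoms only by default — this also keeps pocket membership independent of
the protonation model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import LigandInstance, ModelError, Residue, StructureModel

__all__ = ["PocketDefinition", "OccurrenceTable", "pocket_residues",
           "occurrence_table", "arm_assignment"]

ResidueKey = tuple[str, int]  # (three-letter name, author number)

ARM_ORDER = ("I", "II", "III", "entrance")


@dataclass(frozen=True)
class PocketDefinition:
    cutoff: float = 4.5
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ModelError("pocket cutoff must be positive")


@dataclass
class OccurrenceTable:
    """Per-residue occurrence counts across a set of complexes."""

    table: pd.DataFrame  # columns resname, resnum, count, forms_hb
    n_complexes: int
    union: set[ResidueKey]
    intersection: set[ResidueKey]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def pocket_residues(model: StructureModel, ligand: LigandInstance,
                    pocket_def: PocketDefinition = PocketDefinition()
                    ) -> list[ResidueKey]:
    """Protein residues with >= 1 (heavy) atom within the cutoff of the ligand."""
    lig_atoms = (ligand.heavy_atoms if pocket_def.heavy_atoms_only
                 else ligand.atoms)
    if not lig_atoms:
        raise ModelError("ligand has no atoms")
    tree = cKDTree(np.array([a.pos for a in lig_atoms]))
    hits: list[ResidueKey] = []
    for res in model.iter_protein_residues():
        atoms = res.heavy_atoms if pocket_def.heavy_atoms_only else res.atoms
        if not atoms:
            continue
        d, _ = tree.query(np.array([a.pos for a in atoms]), k=1)
        if float(np.min(d)) <= pocket_def.cutoff:
            hits.append((res.name, res.number))
    return sorted(set(hits))


def occurrence_table(
    pairs: Sequence[tuple[StructureModel, LigandInstance]],
    pocket_def: PocketDefinition = PocketDefinition(),
    hb_residues: Optional[set[ResidueKey]] = None,
) -> OccurrenceTable:
    """Aggregate pocket membership across (complex, ligand) pairs.

    ``hb_residues`` optionally flags residues known to hydrogen-bond the
    ligands, mirroring the highlighted bars of an occurrence chart.
    """
    if not pairs:
        raise ModelError("at least one complex-ligand pair required")
    sets = [set(pocket_residues(m, l, pocket_def)) for m, l in pairs]
    union: set[ResidueKey] = set().union(*sets)
    intersection: set[ResidueKey] = set.intersection(*sets)
    counts = {key: sum(key in s for s in sets) for key in union}
    hb_residues = hb_residues or set()
    rows = [{"resname": k[0], "resnum": k[1], "count": counts[k],
             "forms_hb": k in hb_residues}
            for k in sorted(union, key=lambda k: (k[1], k[0]))]
    table = pd.DataFrame(rows, columns=["resname", "resnum", "count", "forms_hb"])
    return OccurrenceTable(table, len(pairs), union, intersection)


def arm_assignment(ligand_atoms: Iterable, arm_refs: Optional[dict[str, np.ndarray]]
                   ) -> list[str]:
    """Label each ligand atom by the nearest arm reference centroid.

    Arms are reporting labels for the Y-shaped pocket (Arm I toward the
    activation helix, Arm II toward the helix-3/beta-sheet side, Arm III
    near the entrance).  Ties go to the lowest-ordered arm.
    """
    if not arm_refs:
        raise ModelError("arm reference points are not configured")
    for label in arm_refs:
        if label not in ARM_ORDER:
            raise ModelError(f"unknown arm label {label!r}; expected {ARM_ORDER}")
    labels_sorted = sorted(arm_refs, key=ARM_ORDER.index)
    out = []
    for atom in ligand_atoms:
        pos = atom.pos if hasattr(atom, "pos") else np.asarray(atom, dtype=float)
        best, best_d = None, None
        for label in labels_sorted:
            d = float(np.linalg.norm(pos - np.asarray(arm_refs[label], dtype=float)))
            if best is None or d < best_d - 1e-12:
                best, best_d = label, d
        out.append(best)
    return out
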