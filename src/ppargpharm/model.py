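"""Domain types for protein/ligand structures.

The coordinate convention throughout the package is the author residue
numbering of the source PDB entry (no renumbering), with positions in
Angstroms.  A :class:`StructureModel` partitions one PDB entry into protein
chains, bound small molecules (het groups) and crystallographic waters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

# Elements treated as valid in coordinate records.  Covers organic chemistry,
# common counter-ions and metals seen in nuclear-receptor entries.
VALID_ELEMENTS = frozenset(
    "H C N O S P F Cl Br I B Se Fe Zn Mg Ca Na K Mn Cu Ni Co Cd Hg D X".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: three letter -> one letter codes for the 20 standard amino acids
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


class ModelError(ValueError):
    """Raised on invalid or inconsistent structural data."""


@dataclass
class Atom:
    """One atom of a coordinate record."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False
    serial: int = 0
    altloc: str = ""
    placed: bool = False  # hydrogen added by the protonation module

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ModelError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.pos)):
            raise ModelError(f"atom {self.name}: non-finite coordinates")
        el = self.element.strip().capitalize()
        if el not in VALID_ELEMENTS:
            raise ModelError(f"atom {self.name}: invalid element {self.element!r}")
        self.element = el

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, pos=self.pos.copy())


@dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    chain_id: str = " "
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity used to aggregate residues across complexes."""
        return (self.name, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}{self.icode}".strip()

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.icode, self.chain_id,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues.sort(key=lambda r: (r.number, r.icode))

    def residue(self, number: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def ca_atoms(self) -> list[tuple[Residue, Atom]]:
        out = []
        for r in self.residues:
            ca = r.atom("CA")
            if ca is not None:
                out.append((r, ca))
        return out

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


Bond = tuple[int, int, int, bool]  # (atom index i, atom index j, order, aromatic)


@dataclass
class LigandInstance:
    """One bound small molecule, addressed by PDB chemical component id."""

    comp_id: str
    chain_id: str
    residue_number: int
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    formal_charges: dict[int, int] = field(default_factory=dict)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms if heavy_only else self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.pos for a in atoms])

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_index(self, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.name == name:
                return i
        raise ModelError(f"ligand {self.comp_id}: no atom named {name!r}")

    def charge_of(self, index: int) -> int:
        return self.formal_charges.get(index, 0)

    def neighbors(self, index: int) -> list[int]:
        out = []
        for i, j, *_ in self.bonds:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return out

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        for b in self.bonds:
            if {b[0], b[1]} == {i, j}:
                return b
        return None

    @property
    def centroid(self) -> np.ndarray:
        return self.coords(heavy_only=True).mean(axis=0)

    @property
    def net_charge(self) -> int:
        return sum(self.formal_charges.values())

    def copy(self) -> "LigandInstance":
        return LigandInstance(
            self.comp_id, self.chain_id, self.residue_number,
            [a.copy() for a in self.atoms], list(self.bonds),
            dict(self.formal_charges),
        )


@dataclass
class StructureModel:
    """All chains, het groups and waters of one PDB entry (model 1)."""

    entry_id: str = ""
    chains: list[Chain] = field(default_factory=list)
    het_groups: list[LigandInstance] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def iter_protein_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_protein_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.iter_protein_residues():
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        n = sum(len(r.atoms) for r in self.iter_protein_residues())
        n += sum(len(l.atoms) for l in self.het_groups)
        n += sum(len(w.atoms) for w in self.waters)
        return n

    def all_atoms(self) -> list[Atom]:
        out: list[Atom] = []
        for r in self.iter_protein_residues():
            out.extend(r.atoms)
        for l in self.het_groups:
            out.extend(l.atoms)
        for w in self.waters:
            out.extend(w.atoms)
        return out

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.entry_id,
            [c.copy() for c in self.chains],
            [l.copy() for l in self.het_groups],
            [w.copy() for w in self.waters],
        )
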