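"""PDB reading/writing, ligand extraction and bond perception.

Reading is backed by gemmi; this module partitions records into protein
chains, het groups and waters, resolves alternate locations (highest
occupancy wins, ties broken alphabetically by altloc) and keeps only the
first MODEL of multi-model files.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request
import warnings
from pathlib import Path
from typing import Optional, Union

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .model import (
    Atom,
    Bond,
    Chain,
    LigandInstance,
    ModelError,
    Residue,
    StructureModel,
    WATER_NAMES,
)

__all__ = [
    "read_pdb", "write_pdb", "extract_ligand", "perceive_ligand_bonds",
    "fetch_structure", "PdbParseError", "FetchError", "LigandNotFoundError",
]

PDB_DOWNLOAD_URL = "https://files.rcsb.org/download/{accession}.pdb"

#: single-bond covalent radii (A); perception cutoff is r_i + r_j + 0.45 A
COVALENT_RADII = {
    "H": 0.31, "D": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "P": 1.07, "S": 1.05, "Cl": 1.02, "Se": 1.20, "Br": 1.20,
    "I": 1.39, "Fe": 1.32, "Zn": 1.22, "Mg": 1.41, "Ca": 1.76, "Na": 1.66,
    "K": 2.03,
}
BOND_TOLERANCE = 0.45
MIN_BOND_DIST = 0.4

# maximum bond length (A) for a ring bond to count as aromatic, by element pair
_AROMATIC_MAX = {
    frozenset({"C"}): 1.45,
    frozenset({"C", "N"}): 1.42,
    frozenset({"N"}): 1.40,
    frozenset({"C", "O"}): 1.40,
    frozenset({"N", "O"}): 1.40,
    frozenset({"C", "S"}): 1.74,
    frozenset({"N", "S"}): 1.70,
}
_AROMATIC_PLANARITY = 0.15  # A, max out-of-plane deviation


class PdbParseError(ModelError):
    pass


class FetchError(RuntimeError):
    pass


class LigandNotFoundError(KeyError):
    pass


def _validate_coordinate_lines(text: str) -> None:
    """Raise PdbParseError naming the first malformed ATOM/HETATM line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PdbParseError(f"line {lineno}: coordinate record too short")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PdbParseError(f"line {lineno}: bad coordinate field ({exc})") from exc


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, tie -> lowest altloc."""
    by_name: dict[str, gemmi.Atom] = {}
    for at in res:
        prev = by_name.get(at.name)
        if prev is None:
            by_name[at.name] = at
        elif (at.occ, -ord(at.altloc or "z")) > (prev.occ, -ord(prev.altloc or "z")):
            by_name[at.name] = at
    return list(by_name.values())


def _convert_atom(at: gemmi.Atom, hetero: bool) -> Atom:
    el = at.element.name if at.element.name else "X"
    return Atom(
        name=at.name,
        element=el,
        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
        occupancy=at.occ,
        is_hetero=hetero,
        serial=at.serial,
        altloc=(at.altloc or "").strip("\x00"),
    )


def read_pdb(source: Union[str, Path]) -> StructureModel:
    """Read a PDB file or PDB-format text into a StructureModel.

    Only MODEL 1 is used.  Alternate locations are resolved to the highest
    occupancy conformer.  Waters (HOH/WAT/DOD) are collected separately from
    polymer chains and het groups; het group bonds are left unperceived.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        text = Path(source).read_text()
        entry_id = Path(source).stem.upper()
    else:
        text = str(source)
        entry_id = ""
    _validate_coordinate_lines(text)

    st = gemmi.read_pdb_string(text)
    if st.name and not entry_id:
        entry_id = st.name.strip().upper()

    model = StructureModel(entry_id=entry_id)
    if len(st) == 0:
        return model
    gm = st[0]  # MODEL 1 only

    for gchain in gm:
        chain = Chain(gchain.name, [])
        for gres in gchain:
            atoms = [_convert_atom(a, gres.het_flag == "H")
                     for a in _resolve_altlocs(gres)]
            resname = gres.name.strip()
            number = gres.seqid.num
            icode = (gres.seqid.icode or "").strip()
            residue = Residue(resname, number, icode, gchain.name, atoms)
            if resname in WATER_NAMES:
                residue.name = "HOH"
                model.waters.append(residue)
            elif gres.het_flag == "H":
                model.het_groups.append(
                    LigandInstance(resname, gchain.name, number, atoms)
                )
            else:
                chain.residues.append(residue)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.number, r.icode))
            model.chains.append(chain)
    return model


def _format_atom_line(record: str, serial: int, name: str, resname: str,
                      chain_id: str, resnum: int, icode: str, atom: Atom) -> str:
    if len(name) > 4:
        raise ModelError(f"atom name {name!r} longer than 4 characters")
    # short names of one-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.pos
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{resname:>3} {chain_id:1}"
        f"{resnum:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
        f"{0.0:6.2f}          {atom.element:>2}"
    )


def write_pdb(model: StructureModel) -> str:
    """Serialise a StructureModel as PDB-format text.

    Coordinates are written with 3 decimals; ``read_pdb(write_pdb(m))``
    preserves coordinates to 0.001 A and all residue identities.
    """
    lines = [f"HEADER    {model.entry_id or 'MODEL'}"]
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line(
                    "ATOM", serial, atom.name, res.name, chain.chain_id,
                    res.number, res.icode or " ", atom))
        serial += 1
        lines.append(f"TER   {serial:>5}")
    for lig in model.het_groups:
        for atom in lig.atoms:
            serial += 1
            lines.append(_format_atom_line(
                "HETATM", serial, atom.name, lig.comp_id, lig.chain_id,
                lig.residue_number, " ", atom))
    for wat in model.waters:
        for atom in wat.atoms:
            serial += 1
            lines.append(_format_atom_line(
                "HETATM", serial, atom.name, "HOH", wat.chain_id,
                wat.number, wat.icode or " ", atom))
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_ligand(model: StructureModel, comp_id: str,
                   chain_id: Optional[str] = None) -> LigandInstance:
    """Return the unique het group with the given component id.

    When two copies of the component are bound (dual-ligand complexes),
    ``chain_id`` must disambiguate; otherwise an error lists the candidates.
    """
    matches = [l for l in model.het_groups if l.comp_id == comp_id]
    if chain_id is not None:
        matches = [l for l in matches if l.chain_id == chain_id]
    if not matches:
        raise LigandNotFoundError(
            f"component {comp_id!r}"
            + (f" in chain {chain_id!r}" if chain_id else "")
            + f" not found in {model.entry_id or 'model'}")
    if len(matches) > 1:
        cands = ", ".join(f"{l.chain_id}/{l.residue_number}" for l in matches)
        raise ModelError(
            f"component {comp_id!r} is ambiguous; candidates: {cands} "
            "(pass chain_id to disambiguate)")
    return matches[0]


def _ring_is_aromatic(ring: list[int], ligand: LigandInstance) -> bool:
    if len(ring) not in (5, 6):
        return False
    atoms = [ligand.atoms[i] for i in ring]
    if any(a.element not in ("C", "N", "O", "S") for a in atoms):
        return False
    coords = np.array([a.pos for a in atoms])
    center = coords.mean(axis=0)
    # best-fit plane normal = smallest right singular vector
    _, _, vt = np.linalg.svd(coords - center)
    deviation = np.abs((coords - center) @ vt[2])
    if deviation.max() > _AROMATIC_PLANARITY:
        return False
    n = len(ring)
    for k in range(n):
        i, j = ring[k], ring[(k + 1) % n]
        pair = frozenset({ligand.atoms[i].element, ligand.atoms[j].element})
        limit = _AROMATIC_MAX.get(pair)
        if limit is None:
            return False
        if np.linalg.norm(ligand.atoms[i].pos - ligand.atoms[j].pos) > limit:
            return False
    return True


def perceive_ligand_bonds(
    ligand: LigandInstance,
    component_dictionary: Optional[Union[str, Path]] = None,
) -> LigandInstance:
    """Perceive covalent bonds (and ring aromaticity) of a het group.

    If an mmCIF chemical-component dictionary entry is supplied, bonds and
    formal charges are copied from it (matched by atom name).  Otherwise
    bonds are perceived from distances — two atoms are bonded when their
    separation is below the sum of covalent radii plus 0.45 A — followed by
    geometric aromaticity perception on 5/6-rings (planarity and
    aromatic-range bond lengths).  Terminal oxygens closer than 1.30 A are
    assigned bond order 2 (carbonyl-like).
    """
    out = ligand.copy()
    if component_dictionary is not None:
        _bonds_from_ccd(out, component_dictionary)
        return out

    n = len(out.atoms)
    out.bonds = []
    if n == 0:
        return out
    coords = np.array([a.pos for a in out.atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 0.77) for a in out.atoms])
    d = cdist(coords, coords)
    limit = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    for i in range(n):
        for j in range(i + 1, n):
            if MIN_BOND_DIST < d[i, j] <= limit[i, j]:
                if out.atoms[i].is_hydrogen and out.atoms[j].is_hydrogen:
                    continue
                out.bonds.append((i, j, 1, False))

    graph = nx.Graph((i, j) for i, j, *_ in out.bonds)
    graph.add_nodes_from(k for k in range(n) if not out.atoms[k].is_hydrogen)
    heavy = [k for k in range(n) if not out.atoms[k].is_hydrogen]
    if heavy and nx.number_connected_components(graph.subgraph(heavy)) > 1:
        warnings.warn(
            f"ligand {out.comp_id}: perceived bond graph is disconnected",
            stacklevel=2)

    # carbonyl-like terminal oxygens
    adj: dict[int, list[int]] = {k: [] for k in range(n)}
    for i, j, *_ in out.bonds:
        adj[i].append(j)
        adj[j].append(i)
    for idx in range(n):
        a = out.atoms[idx]
        if a.element != "O" or len(adj[idx]) != 1:
            continue
        partner = adj[idx][0]
        if d[idx, partner] < 1.30:
            out.bonds = [
                (i, j, 2 if {i, j} == {idx, partner} else order, arom)
                for (i, j, order, arom) in out.bonds
            ]

    # geometric aromaticity on minimum cycle basis rings
    ring_graph = nx.Graph((i, j) for i, j, *_ in out.bonds
                          if not out.atoms[i].is_hydrogen
                          and not out.atoms[j].is_hydrogen)
    aromatic_pairs: set[frozenset[int]] = set()
    if ring_graph.number_of_nodes() > 2:
        for ring in nx.minimum_cycle_basis(ring_graph):
            ring = _order_ring(ring, ring_graph)
            if ring and _ring_is_aromatic(ring, out):
                m = len(ring)
                for k in range(m):
                    aromatic_pairs.add(frozenset({ring[k], ring[(k + 1) % m]}))
    if aromatic_pairs:
        out.bonds = [
            (i, j, order, frozenset({i, j}) in aromatic_pairs or arom)
            for (i, j, order, arom) in out.bonds
        ]
    return out


def _order_ring(nodes: list[int], graph: nx.Graph) -> list[int]:
    """Order a cycle-basis node set into a traversal; [] if not a simple ring."""
    sub = graph.subgraph(nodes)
    if any(sub.degree(v) != 2 for v in nodes):
        return []
    start = nodes[0]
    order = [start]
    prev = None
    cur = start
    while True:
        nbrs = [v for v in sub.neighbors(cur) if v != prev]
        if not nbrs:
            return []
        prev, cur = cur, nbrs[0]
        if cur == start:
            break
        order.append(cur)
    return order if len(order) == len(nodes) else []


def _bonds_from_ccd(ligand: LigandInstance, path: Union[str, Path]) -> None:
    doc = gemmi.cif.read(str(path))
    block = None
    for b in doc:
        if b.find_values("_chem_comp_atom.atom_id"):
            block = b
            break
    if block is None:
        raise ModelError(f"no chemical component definition found in {path}")
    names = [v.strip('"') for v in block.find_values("_chem_comp_atom.atom_id")]
    charges = [int(float(v)) for v in
               block.find_values("_chem_comp_atom.charge")] or [0] * len(names)
    name_to_idx = {}
    for i, a in enumerate(ligand.atoms):
        name_to_idx[a.name] = i
    for nm, q in zip(names, charges):
        if q and nm in name_to_idx:
            ligand.formal_charges[name_to_idx[nm]] = q
    a1 = [v.strip('"') for v in block.find_values("_chem_comp_bond.atom_id_1")]
    a2 = [v.strip('"') for v in block.find_values("_chem_comp_bond.atom_id_2")]
    orders = list(block.find_values("_chem_comp_bond.value_order"))
    aroms = list(block.find_values("_chem_comp_bond.pdbx_aromatic_flag"))
    order_map = {"SING": 1, "DOUB": 2, "TRIP": 3}
    ligand.bonds = []
    for k in range(len(a1)):
        if a1[k] in name_to_idx and a2[k] in name_to_idx:
            ligand.bonds.append((
                name_to_idx[a1[k]], name_to_idx[a2[k]],
                order_map.get(orders[k].upper() if k < len(orders) else "SING", 1),
                (aroms[k].upper() == "Y") if k < len(aroms) else False,
            ))


def fetch_structure(accession: str, cache_dir: Union[str, Path] = "cache",
                    timeout: float = 20.0) -> StructureModel:
    """Fetch a PDB entry by accession, caching at ``cache/<accession>.pdb``.

    Subsequent calls are served from the cache without network access.
    """
    accession = accession.strip().upper()
    if len(accession) != 4 or not accession[0].isdigit():
        raise FetchError(f"{accession!r} is not a valid PDB accession")
    cache = Path(cache_dir)
    cached = cache / f"{accession}.pdb"
    if cached.exists():
        return read_pdb(cached)
    url = PDB_DOWNLOAD_URL.format(accession=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(
            f"could not fetch {accession} from {url} and no cached copy at "
            f"{cached}: {exc}") from exc
    cache.mkdir(parents=True, exist_ok=True)
    cached.write_text(text)
    model = read_pdb(cached)
    model.entry_id = accession
    return model
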