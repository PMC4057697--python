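"""Ligand annotation points, pharmacophore query construction and matching.

Annotation points fall into three categories: atom points located on an
atom (Don, Acc, Cat, Ani, HydA), projected points placed along an implicit
hydrogen or lone-pair direction (Don2, Acc2), and centroid points at the
geometric centre of an atom subset (Aro, PiR for aromatic rings, Hyd for
hydrophobic clusters).  A query feature is an annotation-point kind set
plus a centroid and a non-zero radius encoding the permissible geometric
variation; matching is static — the ligand must already sit in the
template frame and no refitting is performed.

The seven-feature full-agonist model comprises four polar features
(F1, F2, F4, F6: donor/acceptor chemistry) and three hydrophobic/aromatic
features (F3, F5, F7); the classification rule is
``(F1 or F2) and F3 and (F4 or F5 or F6 or F7)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage

from .geometry import unit
from .model import LigandInstance, ModelError

__all__ = [
    "AnnotationPoint", "PharmacophoreFeature", "PharmacophoreQuery",
    "FeatureVector", "MissingHydrogensError", "FrameMismatchError",
    "annotate", "build_query", "match", "screen", "classify_full_agonist",
    "load_feature_spec", "DEFAULT_FEATURE_SPEC_PATH",
]

KINDS = ("Don", "Acc", "Cat", "Ani", "ML", "HydA",
         "Don2", "Acc2", "ML2", "PiN", "Aro", "PiR", "Hyd")

_PROJECTION_LENGTH = 2.8   # A, along ideal H / lone-pair directions
_HYD_LINK = 2.0            # A, greedy hydrophobic cluster link distance
_CLUSTER_LINK = 2.0        # A, complete-linkage threshold in query building

DEFAULT_FEATURE_SPEC_PATH = Path(__file__).parent / "data" / "feature_spec.yaml"


class MissingHydrogensError(ModelError):
    pass


class FrameMismatchError(ModelError):
    pass


@dataclass
class AnnotationPoint:
    kind: str
    position: np.ndarray
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ModelError(f"unknown annotation kind {self.kind!r}")
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class PharmacophoreFeature:
    id: str
    kinds: tuple[str, ...]
    centroid: np.ndarray
    radius: float
    arm: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ModelError(f"feature {self.id}: radius must be non-zero")
        self.centroid = np.asarray(self.centroid, dtype=float)


@dataclass
class PharmacophoreQuery:
    features: list[PharmacophoreFeature]
    frame: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate feature ids in query")

    def feature(self, fid: str) -> PharmacophoreFeature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def to_json(self) -> str:
        return json.dumps({
            "frame": self.frame,
            "provenance": self.provenance,
            "features": [{
                "id": f.id, "kinds": list(f.kinds),
                "centroid": [round(float(x), 6) for x in f.centroid],
                "radius": f.radius, "arm": f.arm,
            } for f in self.features],
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreQuery":
        data = json.loads(text)
        feats = [PharmacophoreFeature(d["id"], tuple(d["kinds"]),
                                      np.array(d["centroid"]), d["radius"],
                                      d.get("arm", ""))
                 for d in data["features"]]
        return cls(feats, data.get("frame", ""), data.get("provenance", {}))


@dataclass
class FeatureVector:
    comp_id: str
    values: tuple[bool, ...]
    matched: dict[str, AnnotationPoint] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.values)

    def as_signs(self) -> str:
        return "".join("+" if v else "-" for v in self.values)


# ---------------------------------------------------------------------------
# annotation

def _attached_h(lig: LigandInstance, i: int) -> list[int]:
    out = [j for j in lig.neighbors(i) if lig.atoms[j].is_hydrogen]
    if out:
        return out
    # fall back to distance when the bond list omits hydrogens
    return [j for j, a in enumerate(lig.atoms)
            if a.is_hydrogen
            and np.linalg.norm(a.pos - lig.atoms[i].pos) <= 1.25]


def _expects_hydrogen(lig: LigandInstance, i: int) -> bool:
    atom = lig.atoms[i]
    heavy = [j for j in lig.neighbors(i) if not lig.atoms[j].is_hydrogen]
    if atom.element == "O" and lig.charge_of(i) == 0 and len(heavy) == 1:
        bond = lig.bond_between(i, heavy[0])
        if bond and bond[2] == 1:
            partner_term_o = [k for k in lig.neighbors(heavy[0])
                              if lig.atoms[k].element == "O"
                              and len([m for m in lig.neighbors(k)
                                       if not lig.atoms[m].is_hydrogen]) == 1]
            return len(partner_term_o) < 2
    if atom.element == "N":
        aromatic = any(b[3] for b in lig.bonds if i in b[:2])
        multiple = any(b[2] >= 2 for b in lig.bonds if i in b[:2])
        if lig.charge_of(i) > 0:
            return True
        if not aromatic and not multiple and 1 <= len(heavy) <= 2:
            return True
    return False


def _hydrophobic_indices(lig: LigandInstance) -> list[int]:
    out = []
    for i, atom in enumerate(lig.atoms):
        if atom.element != "C" or lig.charge_of(i):
            continue
        nbr_elements = {lig.atoms[j].element for j in lig.neighbors(i)}
        if nbr_elements & {"N", "O", "F"}:
            continue
        out.append(i)
    return out


def _aromatic_rings(lig: LigandInstance) -> list[list[int]]:
    import networkx as nx

    g = nx.Graph((i, j) for i, j, _o, arom in lig.bonds if arom)
    rings = []
    for cyc in nx.minimum_cycle_basis(g) if g.number_of_nodes() else []:
        if len(cyc) in (5, 6):
            rings.append(sorted(cyc))
    return rings


def _charged_groups(lig: LigandInstance) -> tuple[list, list, set[int]]:
    """Delocalised charge groups: (anionic groups, cationic groups, covered)."""
    anionic, cationic, covered = [], [], set()
    for i, atom in enumerate(lig.atoms):
        if atom.element != "C":
            continue
        term_o = [j for j in lig.neighbors(i)
                  if lig.atoms[j].element == "O"
                  and len([k for k in lig.neighbors(j)
                           if not lig.atoms[k].is_hydrogen]) == 1]
        if len(term_o) == 2 and sum(lig.charge_of(j) for j in term_o) < 0:
            anionic.append(term_o)
            covered.update(term_o)
        term_n = [j for j in lig.neighbors(i)
                  if lig.atoms[j].element == "N"
                  and len([k for k in lig.neighbors(j)
                           if not lig.atoms[k].is_hydrogen]) == 1]
        if len(term_n) >= 2 and sum(lig.charge_of(j) for j in term_n) > 0:
            cationic.append(term_n)
            covered.update(term_n)
    return anionic, cationic, covered


def annotate(ligand: LigandInstance) -> list[AnnotationPoint]:
    """Generate the annotation points of a ligand.

    Requires perceived bonds; raises :class:`MissingHydrogensError` when a
    nitrogen/oxygen that should carry a hydrogen has none (run the
    protonation module first).
    """
    if not ligand.bonds:
        raise ModelError("ligand has no perceived bonds; run "
                         "perceive_ligand_bonds first")
    points: list[AnnotationPoint] = []
    n = len(ligand.atoms)
    for i in range(n):
        if ligand.atoms[i].element in ("N", "O") and _expects_hydrogen(ligand, i) \
                and not _attached_h(ligand, i):
            raise MissingHydrogensError(
                f"atom {ligand.atoms[i].name} should carry a hydrogen but has "
                "none; run the protonation module before annotating")

    anionic, cationic, covered = _charged_groups(ligand)
    for group in anionic:
        centroid = np.mean([ligand.atoms[j].pos for j in group], axis=0)
        points.append(AnnotationPoint(
            "Ani", centroid, tuple(ligand.atoms[j].name for j in group)))
    for group in cationic:
        centroid = np.mean([ligand.atoms[j].pos for j in group], axis=0)
        points.append(AnnotationPoint(
            "Cat", centroid, tuple(ligand.atoms[j].name for j in group)))

    for i, atom in enumerate(ligand.atoms):
        if atom.is_hydrogen:
            continue
        q = ligand.charge_of(i)
        hs = _attached_h(ligand, i)
        heavy = [j for j in ligand.neighbors(i) if not ligand.atoms[j].is_hydrogen]
        if q > 0 and i not in covered:
            points.append(AnnotationPoint("Cat", atom.pos, (atom.name,)))
        if q < 0 and i not in covered:
            points.append(AnnotationPoint("Ani", atom.pos, (atom.name,)))

        if atom.element in ("N", "O", "S") and hs:
            points.append(AnnotationPoint("Don", atom.pos, (atom.name,)))
            for h in hs:
                direction = unit(ligand.atoms[h].pos - atom.pos)
                points.append(AnnotationPoint(
                    "Don2", atom.pos + _PROJECTION_LENGTH * direction,
                    (atom.name, ligand.atoms[h].name)))
        is_acceptor = False
        if atom.element == "O" and q <= 0:
            is_acceptor = True
        elif atom.element == "N" and not hs and q <= 0 and len(heavy) <= 3:
            is_acceptor = True
        if is_acceptor:
            points.append(AnnotationPoint("Acc", atom.pos, (atom.name,)))
            anchors = heavy or ligand.neighbors(i)
            if anchors:
                direction = -np.sum([unit(ligand.atoms[j].pos - atom.pos)
                                     for j in anchors], axis=0)
                if np.linalg.norm(direction) > 1e-6:
                    points.append(AnnotationPoint(
                        "Acc2",
                        atom.pos + _PROJECTION_LENGTH * unit(direction),
                        (atom.name,)))

    for ring in _aromatic_rings(ligand):
        centroid = np.mean([ligand.atoms[j].pos for j in ring], axis=0)
        parents = tuple(ligand.atoms[j].name for j in ring)
        points.append(AnnotationPoint("Aro", centroid, parents))
        points.append(AnnotationPoint("PiR", centroid, parents))

    hydro = _hydrophobic_indices(ligand)
    for i in hydro:
        points.append(AnnotationPoint("HydA", ligand.atoms[i].pos,
                                      (ligand.atoms[i].name,)))
    for cluster in _link_clusters(ligand, hydro, _HYD_LINK):
        centroid = np.mean([ligand.atoms[j].pos for j in cluster], axis=0)
        points.append(AnnotationPoint(
            "Hyd", centroid, tuple(ligand.atoms[j].name for j in cluster)))
    return points


def _link_clusters(lig: LigandInstance, indices: list[int],
                   link: float) -> list[list[int]]:
    """Greedy single-linkage clusters of the given atoms."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(indices)
    for a in range(len(indices)):
        for b in range(a + 1, len(indices)):
            i, j = indices[a], indices[b]
            if np.linalg.norm(lig.atoms[i].pos - lig.atoms[j].pos) <= link:
                g.add_edge(i, j)
    return [sorted(c) for c in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# query construction and matching

def load_feature_spec(path: Union[str, Path] = DEFAULT_FEATURE_SPEC_PATH
                      ) -> list[dict]:
    data = yaml.safe_load(Path(path).read_text())
    return data["features"]


def build_query(
    actives: Sequence[tuple[str, Sequence[AnnotationPoint]]],
    feature_spec: Optional[Sequence[dict]] = None,
    radius: float = 1.2,
    radius_overrides: Optional[dict[str, float]] = None,
    arm_refs: Optional[dict[str, np.ndarray]] = None,
    frame: str = "",
) -> PharmacophoreQuery:
    """Build the query from the annotation points of aligned active ligands.

    For each specified feature, points of the allowed kinds from all
    actives are complete-linkage clustered at 2.0 A; the cluster supported
    by the most distinct actives (restricted to the stated arm when arm
    reference points are configured) becomes the feature centroid.  Ties
    are broken by distance to the arm reference point, then by coordinates.
    """
    if not actives:
        raise ModelError("at least one active ligand required")
    spec = list(feature_spec) if feature_spec is not None else load_feature_spec()
    radius_overrides = radius_overrides or {}
    features = []
    for fdef in spec:
        fid = fdef["id"]
        kinds = tuple(fdef["kinds"])
        arm = fdef.get("arm", "")
        pts, owners = [], []
        for name, points in actives:
            for p in points:
                if p.kind in kinds:
                    pts.append(p.position)
                    owners.append(name)
        if not pts:
            raise ModelError(f"no supporting annotation points for mandatory "
                             f"feature {fid}")
        centroid = _best_cluster(np.array(pts), owners, arm, arm_refs)
        features.append(PharmacophoreFeature(
            fid, kinds, centroid, radius_overrides.get(fid, radius), arm))
    return PharmacophoreQuery(
        features, frame=frame,
        provenance={"actives": [name for name, _ in actives],
                    "radius": radius,
                    "radius_overrides": dict(radius_overrides)})


def _best_cluster(pts: np.ndarray, owners: list[str], arm: str,
                  arm_refs: Optional[dict[str, np.ndarray]]) -> np.ndarray:
    if len(pts) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(pts, method="complete"),
                          t=_CLUSTER_LINK, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        mask = labels == lab
        support = len({o for o, m in zip(owners, mask) if m})
        clusters.append((support, pts[mask].mean(axis=0)))
    if arm_refs and arm in arm_refs:
        ref = np.asarray(arm_refs[arm], dtype=float)
        in_arm = [c for c in clusters
                  if _nearest_arm(c[1], arm_refs) == arm]
        pool = in_arm or clusters
        pool.sort(key=lambda c: (-c[0], float(np.linalg.norm(c[1] - ref)),
                                 tuple(np.round(c[1], 6))))
    else:
        pool = sorted(clusters,
                      key=lambda c: (-c[0], tuple(np.round(c[1], 6))))
    return pool[0][1]


def _nearest_arm(pos: np.ndarray, arm_refs: dict[str, np.ndarray]) -> str:
    return min(arm_refs,
               key=lambda a: float(np.linalg.norm(pos - np.asarray(arm_refs[a]))))


def match(query: PharmacophoreQuery,
          points: Sequence[AnnotationPoint],
          comp_id: str = "",
          frame_tolerance: float = 25.0) -> FeatureVector:
    """Static matching of a ligand's annotation points against the query.

    A feature is satisfied when at least one point of an allowed kind lies
    within the feature radius of the feature centroid.  When every point
    is farther than ``frame_tolerance`` from every feature centroid the
    ligand clearly was not transformed into the query frame and a
    :class:`FrameMismatchError` is raised.
    """
    points = list(points)
    if points:
        all_pos = np.array([p.position for p in points])
        centroids = np.array([f.centroid for f in query.features])
        dmin = np.min(np.linalg.norm(
            all_pos[:, None, :] - centroids[None, :, :], axis=2))
        if dmin > frame_tolerance:
            raise FrameMismatchError(
                f"nearest annotation point is {dmin:.1f} A from the query; "
                "transform the ligand into the template frame first")
    values, matched = [], {}
    for feat in query.features:
        hit = None
        for p in points:
            if p.kind not in feat.kinds:
                continue
            if np.linalg.norm(p.position - feat.centroid) <= feat.radius:
                hit = p
                break
        values.append(hit is not None)
        if hit is not None:
            matched[feat.id] = hit
    return FeatureVector(comp_id, tuple(values), matched)


def classify_full_agonist(vector: Union[FeatureVector, Sequence[bool]]
                          ) -> tuple[bool, str]:
    """Apply the mandatory-feature rule for full agonism.

    True iff (F1 or F2) and F3 and at least one of F4-F7; the explanation
    lists every failed clause.
    """
    values = tuple(vector.values if isinstance(vector, FeatureVector)
                   else vector)
    if len(values) != 7:
        raise ModelError("feature vector must have length 7")
    f1, f2, f3, f4, f5, f6, f7 = (bool(v) for v in values)
    failed = []
    if not (f1 or f2):
        failed.append("F1 or F2")
    if not f3:
        failed.append("F3")
    if not (f4 or f5 or f6 or f7):
        failed.append("at least one of F4-F7")
    ok = not failed
    explanation = ("full-agonist pattern satisfied" if ok
                   else "failed clauses: " + "; ".join(failed))
    return ok, explanation


def screen(query: PharmacophoreQuery,
           ligands: Sequence[tuple[str, Sequence[AnnotationPoint]]],
           ec50: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Match a set of aligned ligands and tabulate feature vectors.

    Rows are ordered by the EC50 lower bound when an activity table with
    columns (ligand, ec50_low_nM) is provided.  The returned frame carries
    one +/- column per feature plus the classification.
    """
    fids = [f.id for f in query.features]
    rows = []
    for comp_id, points in ligands:
        vec = match(query, points, comp_id=comp_id)
        ok, _why = classify_full_agonist(vec) if len(fids) == 7 else (None, "")
        row = {"ligand": comp_id}
        row.update({fid: ("+" if v else "-")
                    for fid, v in zip(fids, vec.values)})
        row["n_features"] = int(sum(vec.values))
        row["full_agonist"] = ok
        rows.append(row)
    table = pd.DataFrame(rows)
    if ec50 is not None and not table.empty:
        order = {l: v for l, v in zip(ec50["ligand"], ec50["ec50_low_nM"])}
        table["_ec50"] = [order.get(l, np.inf) for l in table["ligand"]]
        table = table.sort_values(["_ec50", "ligand"]).drop(columns="_ec50")
        table = table.reset_index(drop=True)
    return table
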