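"""Configuration-driven orchestration of the full analysis workflow.

A run takes a template complex plus a list of agonist complexes (local PDB
paths or accessions resolved through the fetch cache), and produces:
superposition RMSD table and histogram, binding-pocket occurrence tables,
ligand-interaction reports, activation-helix unique-contact tables, and
the pharmacophore build/screen/classification outputs.  All machine
output goes to files; logs go to stderr.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import binding_pocket, interactions, pharmacophore, protonation
from . import structure_io, superposition
from .model import ModelError, StructureModel

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_EC50_TABLE = _DATA_DIR / "table2_ec50.csv"


class ConfigError(ValueError):
    pass


@dataclass
class EntrySpec:
    id: str
    ligand: Optional[str] = None
    chain: Optional[str] = None
    path: Optional[str] = None


@dataclass
class PipelineConfig:
    template: EntrySpec
    entries: list[EntrySpec] = field(default_factory=list)
    apo: Optional[EntrySpec] = None
    actives: list[str] = field(default_factory=list)   # entry ids for the query
    pocket_cutoff: float = 4.5
    hb_distance: float = 3.5
    hb_angle: float = 120.0
    feature_radius: float = 1.2
    radius_overrides: dict = field(default_factory=dict)
    arm_refs: Optional[dict] = None
    helix_annotation_path: Optional[str] = None
    ec50_table_path: Optional[str] = None
    protonation_overrides: dict = field(default_factory=dict)
    cache_dir: str = "cache"
    out_dir: str = "outputs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pocket_cutoff <= 0 or self.hb_distance <= 0:
            raise ConfigError("cutoffs must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "template" not in raw:
            raise ConfigError("config must define a template entry")

        def entry(d) -> EntrySpec:
            if isinstance(d, str):
                return EntrySpec(id=d)
            return EntrySpec(id=str(d["id"]), ligand=d.get("ligand"),
                             chain=d.get("chain"), path=d.get("path"))

        cfg = cls(
            template=entry(raw["template"]),
            entries=[entry(e) for e in raw.get("entries", [])],
            apo=entry(raw["apo"]) if raw.get("apo") else None,
            actives=[str(a) for a in raw.get("actives", [])],
            pocket_cutoff=float(raw.get("pocket_cutoff", 4.5)),
            hb_distance=float(raw.get("hb_distance", 3.5)),
            hb_angle=float(raw.get("hb_angle", 120.0)),
            feature_radius=float(raw.get("feature_radius", 1.2)),
            radius_overrides=raw.get("radius_overrides", {}) or {},
            arm_refs=raw.get("arm_refs"),
            helix_annotation_path=raw.get("helix_annotation"),
            ec50_table_path=raw.get("ec50_table"),
            protonation_overrides=raw.get("protonation", {}).get(
                "charge_overrides", {}) if raw.get("protonation") else {},
            cache_dir=str(raw.get("cache_dir", "cache")),
            out_dir=str(raw.get("out_dir", "outputs")),
            seed=int(raw.get("seed", 0)),
        )
        for spec in [cfg.template, *cfg.entries] + ([cfg.apo] if cfg.apo else []):
            if spec.path and not Path(spec.path).exists():
                raise ConfigError(f"path {spec.path!r} for entry {spec.id} "
                                  "does not exist")
        return cfg


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, status: str, outputs: Optional[list[str]] = None,
            rows: Optional[int] = None, warning: Optional[str] = None) -> None:
        self.stages.append({"stage": name, "status": status,
                            "outputs": outputs or [], "rows": rows,
                            "warning": warning})

    @property
    def failed(self) -> bool:
        return any(s["status"] == "failed" for s in self.stages)

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({"stages": self.stages}, indent=1)
                              + "\n")


def load_entry(spec: EntrySpec, cache_dir: str) -> StructureModel:
    if spec.path:
        model = structure_io.read_pdb(Path(spec.path))
        model.entry_id = spec.id
        return model
    return structure_io.fetch_structure(spec.id, cache_dir=cache_dir)


def cmd_fetch(config: PipelineConfig) -> tuple[int, list[str]]:
    """Cache every configured entry; returns (n_failures, messages)."""
    messages = []
    failures = 0
    specs = [config.template, *config.entries]
    if config.apo:
        specs.append(config.apo)
    for spec in specs:
        if spec.path:
            messages.append(f"{spec.id}: local path, skipped")
            continue
        try:
            structure_io.fetch_structure(spec.id, cache_dir=config.cache_dir)
            messages.append(f"{spec.id}: cached")
        except structure_io.FetchError as exc:
            failures += 1
            messages.append(f"{spec.id}: FAILED ({exc})")
    return failures, messages


def _ligand_in_frame(model: StructureModel, spec: EntrySpec,
                     template_centroid: Optional[np.ndarray]):
    """Extract the entry's ligand.  The configured chain names the receptor
    chain, so it only narrows the search when the component is bound there;
    dual copies are otherwise resolved toward the template ligand centroid."""
    if spec.ligand is None:
        return None
    candidates = [l for l in model.het_groups if l.comp_id == spec.ligand]
    if not candidates:
        raise structure_io.LigandNotFoundError(
            f"component {spec.ligand!r} not found in {model.entry_id}")
    if len(candidates) > 1 and spec.chain:
        in_chain = [l for l in candidates if l.chain_id == spec.chain]
        if in_chain:
            candidates = in_chain
    if len(candidates) > 1:
        if template_centroid is None:
            raise ModelError(
                f"component {spec.ligand!r} is ambiguous in {model.entry_id} "
                "and no template ligand is available to disambiguate")
        candidates = [min(candidates, key=lambda l: float(
            np.linalg.norm(l.centroid - template_centroid)))]
    return structure_io.perceive_ligand_bonds(candidates[0])


def cmd_analyze(config: PipelineConfig) -> RunReport:
    """Run superposition, pocket, interaction and contact analysis."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    template = load_entry(config.template, config.cache_dir)
    tchain_id = config.template.chain or template.chains[0].chain_id
    tchain = template.chain(tchain_id)
    if tchain is None:
        raise ConfigError(f"template chain {tchain_id!r} absent")

    models = []
    for spec in config.entries:
        try:
            models.append(load_entry(spec, config.cache_dir))
        except Exception as exc:
            report.add(f"load:{spec.id}", "failed", warning=str(exc))
    table, transformed = superposition.superpose_all(
        tchain, models,
        chain_overrides={e.id: e.chain for e in config.entries if e.chain})
    rmsd_path = out / "superposition_rmsd.csv"
    table.to_csv(rmsd_path, index=False)
    hist = superposition.rmsd_histogram(table["rmsd_A"].dropna())
    hist_path = out / "rmsd_histogram.csv"
    hist.to_csv(hist_path, index=False)
    report.add("superpose", "ok", [str(rmsd_path), str(hist_path)], len(table))

    annotation = (interactions.HelixAnnotation.from_yaml(
        config.helix_annotation_path) if config.helix_annotation_path
        else interactions.default_helix_annotation())
    criteria = interactions.HBCriteria(config.hb_distance, config.hb_angle)

    template_ligand = None
    if config.template.ligand:
        template_ligand = _ligand_in_frame(template, config.template, None)
    t_centroid = template_ligand.centroid if template_ligand is not None else None

    pairs, ligand_points, hb_rows = [], {}, []
    for spec in config.entries:
        model = transformed.get(spec.id)
        if model is None or spec.ligand is None:
            continue
        try:
            assignment = protonation.assign_ionization(
                model, ligand_overrides=config.protonation_overrides)
            model = protonation.place_polar_hydrogens(model, assignment)
            ligand = _ligand_in_frame(model, spec, t_centroid)
            pairs.append(((spec.id, model, ligand)))
            for hb in interactions.find_hbonds(model, ligand, criteria,
                                               annotation):
                hb_rows.append({
                    "accession": spec.id, "ligand": spec.ligand,
                    "donor": str(hb.donor), "acceptor": str(hb.acceptor),
                    "distance_A": hb.distance, "angle_deg": hb.angle,
                    "direction": hb.direction,
                    "helix_donor": hb.helix_donor,
                    "helix_acceptor": hb.helix_acceptor})
            ligand_points[spec.ligand] = pharmacophore.annotate(ligand)
        except Exception as exc:
            report.add(f"interactions:{spec.id}", "failed", warning=str(exc))

    if pairs:
        occ = binding_pocket.occurrence_table(
            [(m, l) for _id, m, l in pairs],
            binding_pocket.PocketDefinition(config.pocket_cutoff))
        occ_path = out / "pocket_occurrence.csv"
        occ.to_csv(occ_path)
        member_rows = []
        for _id, m, l in pairs:
            in_pocket = set(binding_pocket.pocket_residues(
                m, l, binding_pocket.PocketDefinition(config.pocket_cutoff)))
            member_rows.append({"accession": _id, **{
                f"{k[0]}{k[1]}": (k in in_pocket) for k in sorted(occ.union)}})
        member_path = out / "pocket_membership.csv"
        pd.DataFrame(member_rows).to_csv(member_path, index=False)
        report.add("pockets", "ok", [str(occ_path), str(member_path)],
                   len(occ.table))
    hb_path = out / "hbonds.csv"
    pd.DataFrame(hb_rows, columns=[
        "accession", "ligand", "donor", "acceptor", "distance_A", "angle_deg",
        "direction", "helix_donor", "helix_acceptor"]).to_csv(hb_path,
                                                              index=False)
    report.add("hbonds", "ok", [str(hb_path)], len(hb_rows))

    # activation-helix contacts vs apo reference
    try:
        holo_records = []
        for _id, m, _l in pairs:
            for rec in interactions.helix_contacts(m, annotation, criteria):
                holo_records.append((_id, rec))
        apo_records = []
        if config.apo:
            apo_model = load_entry(config.apo, config.cache_dir)
            assignment = protonation.assign_ionization(apo_model)
            apo_model = protonation.place_polar_hydrogens(apo_model, assignment)
            apo_records = interactions.helix_contacts(apo_model, annotation,
                                                      criteria)
        uniq = interactions.unique_contacts([r for _a, r in holo_records],
                                            apo_records)
        uniq_keys = {r.key for r in uniq}
        rows = [{
            "accession": acc,
            "residue_a": f"{r.residue_a[0]}{r.residue_a[1]}",
            "helix_a": r.helix_a,
            "residue_b": f"{r.residue_b[0]}{r.residue_b[1]}",
            "helix_b": r.helix_b, "type": r.kind, "distance_A": r.distance,
            "unique_vs_apo": r.key in uniq_keys,
        } for acc, r in holo_records]
        contact_path = out / "h12_contacts.csv"
        pd.DataFrame(rows, columns=[
            "accession", "residue_a", "helix_a", "residue_b", "helix_b",
            "type", "distance_A", "unique_vs_apo"]).to_csv(contact_path,
                                                           index=False)
        report.add("h12_contacts", "ok", [str(contact_path)], len(rows))
    except Exception as exc:
        report.add("h12_contacts", "failed", warning=str(exc))

    report.write(out / "run_report.json")
    return report


def cmd_pharm_build(config: PipelineConfig) -> pharmacophore.PharmacophoreQuery:
    """Build the query from the configured active complexes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = cmd_analyze_minimal_for_pharm(config)
    actives_ids = config.actives or [e.id for e in config.entries[:3]]
    actives = []
    for eid in actives_ids:
        if eid not in report:
            raise ConfigError(f"active entry {eid!r} was not analysed; run "
                              "analyze first or fix the config")
        actives.append(report[eid])
    arm_refs = ({k: np.asarray(v, dtype=float)
                 for k, v in config.arm_refs.items()}
                if config.arm_refs else None)
    query = pharmacophore.build_query(
        actives, radius=config.feature_radius,
        radius_overrides=config.radius_overrides, arm_refs=arm_refs,
        frame=f"{config.template.id}:{config.template.chain or ''}")
    (out / "pharmacophore_query.json").write_text(query.to_json() + "\n")
    return query


def cmd_analyze_minimal_for_pharm(config: PipelineConfig
                                  ) -> dict[str, tuple[str, list]]:
    """Aligned, protonated, annotated ligands per entry id."""
    template = load_entry(config.template, config.cache_dir)
    tchain = template.chain(config.template.chain
                            or template.chains[0].chain_id)
    models = [load_entry(e, config.cache_dir) for e in config.entries]
    _table, transformed = superposition.superpose_all(
        tchain, models,
        chain_overrides={e.id: e.chain for e in config.entries if e.chain})
    template_ligand = (_ligand_in_frame(template, config.template, None)
                       if config.template.ligand else None)
    t_centroid = (template_ligand.centroid
                  if template_ligand is not None else None)
    out = {}
    for spec in config.entries:
        model = transformed.get(spec.id)
        if model is None or spec.ligand is None:
            continue
        assignment = protonation.assign_ionization(
            model, ligand_overrides=config.protonation_overrides)
        model = protonation.place_polar_hydrogens(model, assignment)
        ligand = _ligand_in_frame(model, spec, t_centroid)
        out[spec.id] = (spec.ligand, pharmacophore.annotate(ligand))
    return out


def cmd_pharm_screen(config: PipelineConfig,
                     query_path: Optional[Union[str, Path]] = None
                     ) -> pd.DataFrame:
    out = Path(config.out_dir)
    qpath = Path(query_path) if query_path else out / "pharmacophore_query.json"
    if not qpath.exists():
        raise ConfigError(
            f"no pharmacophore query at {qpath}; run 'pharm build' first")
    query = pharmacophore.PharmacophoreQuery.from_json(qpath.read_text())
    annotated = cmd_analyze_minimal_for_pharm(config)
    ec50 = pd.read_csv(config.ec50_table_path or DEFAULT_EC50_TABLE)
    table = pharmacophore.screen(query, list(annotated.values()), ec50=ec50)
    table.to_csv(out / "screen_matrix.csv", index=False)
    return table


def cmd_pharm_classify(vectors: pd.DataFrame) -> pd.DataFrame:
    """Classify +/- feature-vector rows (columns F1..F7)."""
    fids = [f"F{i}" for i in range(1, 8)]
    rows = []
    for _idx, row in vectors.iterrows():
        values = [str(row[f]).strip() == "+" for f in fids]
        ok, why = pharmacophore.classify_full_agonist(values)
        rows.append({"ligand": row.get("ligand", ""),
                     **{f: ("+" if v else "-") for f, v in zip(fids, values)},
                     "full_agonist": ok, "explanation": why})
    return pd.DataFrame(rows)
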