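"""End-to-end annotation pipeline: structures in, annotation tables out.

For every input structure: parse, detect and number V/C domains on both
the deposited and the coordinate-resolved sequence, consolidate species
with the override margin, assign isotype/light-chain type, classify
structural coverage, pair heavy with light chains by interface burial,
and compute packing angles, CH1-CL contact matrices, interfaces, and
disulfides.  Failures are isolated per entry (a malformed file must not
abort a batch build); rows are sorted so output bytes are independent of
input ordering.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import (ChainAnnotation, StructureRecord, assign_isotype,
                       classify_coverage, consolidate_species, flag_engineered,
                       humanized_evidence, species_identity_table)
from .errors import FabkitError
from .numbering import DomainHit, classify_chain, detect_domains, number_domain
from .refdata import ReferenceSet, load_gapped_fasta
from .search import SearchIndex, SearchRecord, build_index
from .structgeom import (ChainCoordinates, ContactMatrix, ParsedStructure,
                         contact_matrix, hl_interface, disulfide_bonds,
                         labeled_ca, packing_angles, read_structure)

log = logging.getLogger("fabkit")


@dataclass
class PipelineConfig:
    reference_fasta: str = ""
    metadata_mode: str = "header_fields"
    min_identity: float = 50.0
    min_length: int = 50
    override_margin: float = 8.0
    contact_cutoff: float = 8.0
    delta_sasa_threshold: float = 1.0
    disulfide_cutoff: float = 2.5
    max_batch: int = 200
    angle_convention: str = "raw"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_length", "override_margin",
                     "contact_cutoff", "delta_sasa_threshold",
                     "disulfide_cutoff", "max_batch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name} must be positive")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AnnotatedStructure:
    record: StructureRecord
    parsed: ParsedStructure
    numbered: dict[str, dict[str, tuple[DomainHit, object]]] = field(default_factory=dict)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    geometry: list[dict] = field(default_factory=list)
    search_records: list[SearchRecord] = field(default_factory=list)


def _domain_maps(chain: ChainCoordinates, refs: ReferenceSet,
                 cfg: PipelineConfig) -> dict[str, tuple[DomainHit, object, dict]]:
    """Detect/number domains on the ATOM sequence and build labelled CA maps."""
    out: dict[str, tuple] = {}
    hits = detect_domains(chain.atom_seq, refs, cfg.min_identity, cfg.min_length)
    for hit in hits:
        span = chain.atom_seq[hit.query_start - 1:hit.query_end]
        numbered = number_domain(span, hit)
        camap = labeled_ca(chain, hit, numbered, atom_space=True)
        if hit.domain_label not in out:
            out[hit.domain_label] = (hit, numbered, camap)
    return out


def annotate_structure(parsed: ParsedStructure, refs: ReferenceSet,
                       cfg: PipelineConfig,
                       provided_species: str = "") -> AnnotatedStructure:
    record = StructureRecord(entry_id=parsed.entry_id,
                             provided_species=provided_species)
    atom_domains: dict[str, dict] = {}
    for cid, chain in sorted(parsed.chains.items()):
        record.seqres_seq[cid] = chain.seqres_seq
        record.atom_seq[cid] = chain.atom_seq
        seq_hits = detect_domains(chain.seqres_seq, refs, cfg.min_identity,
                                  cfg.min_length)
        ann = ChainAnnotation(chain_id=cid, chain_class="ambiguous")
        if not seq_hits:
            ann.notes.append("no domain hits above thresholds")
            record.chains.append(ann)
            continue
        ann.hits = seq_hits
        ann.chain_class = classify_chain(seq_hits)
        labels = {h.domain_label for h in seq_hits}
        if "V" in labels and not labels & {"CH1", "CH2", "CH3", "CH4", "CL"}:
            ann.notes.append("V-only, out of V+C scope")
        # species per domain
        per_domain: dict[str, dict[str, float]] = {}
        v_span = None
        for h in seq_hits:
            span = chain.seqres_seq[h.query_start - 1:h.query_end]
            if h.domain_label == "V" and v_span is None:
                v_span = span
            table = species_identity_table(span, refs, h.domain_label)
            per_domain[h.domain_label] = {sp: ident for sp, (ident, _) in table.items()}
        consolidated, table = consolidate_species(per_domain, provided_species,
                                                  cfg.override_margin)
        ann.per_domain_species = table
        ann.consolidated_species = consolidated
        domain_species = {d: sp for d, (sp, _) in table.items()}
        try:
            mixed = bool(v_span) and humanized_evidence(v_span, refs)
            ann.engineered_flag = flag_engineered(domain_species, mixed)
            if ann.engineered_flag == "humanized":
                ann.notes.append("humanized call is heuristic (mixed V evidence)")
        except FabkitError:
            ann.engineered_flag = "unresolved"
        c_hits = [h for h in seq_hits if h.allele.gene_class == "C"]
        if c_hits:
            ann.isotype_or_lctype, ann.c_allele = assign_isotype(c_hits)
        record.chains.append(ann)
        atom_domains[cid] = _domain_maps(chain, refs, cfg)

    resolved = set()
    for maps in atom_domains.values():
        resolved |= set(maps.keys())
    record.coverage_class = classify_coverage(resolved)

    out = AnnotatedStructure(record=record, parsed=parsed)
    out.numbered = atom_domains
    _pair_and_measure(out, refs, cfg)
    return out


def _pair_and_measure(ann: AnnotatedStructure, refs: ReferenceSet,
                      cfg: PipelineConfig) -> None:
    """Pair H with K/L chains by interface burial, then compute geometry."""
    by_class: dict[str, list[str]] = {"H": [], "light": []}
    chain_class = {c.chain_id: c.chain_class for c in ann.record.chains}
    for cid, cls in chain_class.items():
        if cls == "H":
            by_class["H"].append(cid)
        elif cls in ("K", "L"):
            by_class["light"].append(cid)
    candidates = []
    for h in by_class["H"]:
        for l in by_class["light"]:
            try:
                burial = hl_interface(ann.parsed.chains[h], ann.parsed.chains[l],
                                      cfg.delta_sasa_threshold).buried_area
            except FabkitError:
                burial = 0.0
            candidates.append((burial, h, l))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_h: set[str] = set()
    used_l: set[str] = set()
    for burial, h, l in candidates:
        if h in used_h or l in used_l:
            continue
        used_h.add(h)
        used_l.add(l)
        ann.pairs.append((h, l))
        ann.geometry.append(_pair_geometry(ann, refs, cfg, h, l, burial))
    bonds = disulfide_bonds(ann.parsed, cfg.disulfide_cutoff)
    for g in ann.geometry:
        g["n_disulfides"] = len(bonds)
    _build_search_records(ann)


def _pair_geometry(ann: AnnotatedStructure, refs: ReferenceSet,
                   cfg: PipelineConfig, h: str, l: str, burial: float) -> dict:
    maps_h = ann.numbered.get(h, {})
    maps_l = ann.numbered.get(l, {})
    geo: dict = {"entry_id": ann.record.entry_id, "h_chain": h, "l_chain": l,
                 "buried_area": round(burial, 2), "elbow_deg": None,
                 "ch1_cl_deg": None, "n_ch1_cl_contacts": None}
    vh = maps_h.get("V", (None, None, None))[2]
    vl = maps_l.get("V", (None, None, None))[2]
    ch1 = maps_h.get("CH1", (None, None, None))[2]
    cl = maps_l.get("CL", (None, None, None))[2]
    if all(x for x in (vh, vl, ch1, cl)):
        try:
            angles = packing_angles(vh, vl, ch1, cl, cfg.angle_convention)
            geo["elbow_deg"] = round(angles.elbow_deg, 3)
            geo["ch1_cl_deg"] = round(angles.ch1_cl_deg, 3)
        except FabkitError as exc:
            geo["geometry_note"] = str(exc)
    if ch1 and cl:
        cm = contact_matrix(ch1, cl, cfg.contact_cutoff)
        geo["n_ch1_cl_contacts"] = len(cm.contact_pairs())
        geo["_ch1_cl_matrix"] = cm
    return geo


def _build_search_records(ann: AnnotatedStructure) -> None:
    for (h, l), geo in zip(ann.pairs, ann.geometry):
        rec = SearchRecord(entry_id=ann.record.entry_id, h_chain_id=h, l_chain_id=l)
        maps_h = ann.numbered.get(h, {})
        maps_l = ann.numbered.get(l, {})
        if "V" in maps_h:
            rec.h_v = maps_h["V"][1].sequence
        c_label = next((d for d in ("CH1",) if d in maps_h), None)
        if c_label:
            rec.h_c = maps_h[c_label][1].sequence
        if "V" in maps_l:
            rec.l_v = maps_l["V"][1].sequence
        if "CL" in maps_l:
            rec.l_c = maps_l["CL"][1].sequence
        rec.ch1_cl = geo.get("_ch1_cl_matrix")
        ann.search_records.append(rec)


@dataclass
class PipelineResult:
    annotated: list[AnnotatedStructure] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)
    index: SearchIndex | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def _metadata_lines(cfg: PipelineConfig) -> list[str]:
    lines = [f"# fabkit {__version__}"]
    for key, val in sorted(cfg.as_dict().items()):
        lines.append(f"# {key} = {val}")
    return lines


def run_pipeline(cfg: PipelineConfig, structure_paths: list[str | Path],
                 out_dir: str | Path,
                 metadata: dict[str, str] | None = None) -> PipelineResult:
    """Annotate a batch of structures and write the CSV outputs.

    ``metadata`` optionally maps entry stems to a provided species (the
    depositor annotation the override rule tests against).  Outputs:
    ``annotations.csv`` (one row per H-L pair), ``geometry.csv``, and
    ``index.json`` (the sequence-search views).  Per-entry failures are
    logged and collected; they do not abort the batch.
    """
    if not structure_paths:
        raise ValueError("run_pipeline requires at least one structure path")
    refs = load_gapped_fasta(cfg.reference_fasta, metadata_mode=cfg.metadata_mode)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metadata = metadata or {}
    result = PipelineResult()
    for path in sorted(Path(p) for p in structure_paths):
        try:
            parsed = read_structure(path)
            provided = metadata.get(parsed.entry_id, metadata.get(path.stem, ""))
            result.annotated.append(annotate_structure(parsed, refs, cfg, provided))
        except (FabkitError, ValueError, OSError) as exc:
            log.error("entry %s failed: %s", path.name, exc)
            result.failures[path.name] = str(exc)
    result.annotated.sort(key=lambda a: a.record.entry_id)

    header = _metadata_lines(cfg)
    ann_path = out_dir / "annotations.csv"
    with open(ann_path, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["entry_id", "h_chain", "l_chain", "isotype",
                         "light_type", "species", "engineered_flag",
                         "coverage_class", "h_v_identity", "h_c_identity",
                         "l_v_identity", "l_c_identity"])
        for ann in result.annotated:
            chain_by_id = {c.chain_id: c for c in ann.record.chains}
            for h, l in ann.pairs:
                ch, cl = chain_by_id[h], chain_by_id[l]
                idents = {}
                for tag, c in (("h", ch), ("l", cl)):
                    v_hit = next((x for x in c.hits if x.domain_label == "V"), None)
                    c_hit = next((x for x in c.hits
                                  if x.allele.gene_class == "C"), None)
                    idents[f"{tag}_v"] = round(v_hit.percent_identity, 1) if v_hit else ""
                    idents[f"{tag}_c"] = round(c_hit.percent_identity, 1) if c_hit else ""
                writer.writerow([
                    ann.record.entry_id, h, l, ch.isotype_or_lctype,
                    cl.isotype_or_lctype, ch.consolidated_species,
                    ch.engineered_flag, ann.record.coverage_class,
                    idents["h_v"], idents["h_c"], idents["l_v"], idents["l_c"]])

    geo_path = out_dir / "geometry.csv"
    with open(geo_path, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["entry_id", "h_chain", "l_chain", "elbow_deg",
                         "ch1_cl_deg", "n_ch1_cl_contacts", "buried_area",
                         "n_disulfides"])
        for ann in result.annotated:
            for geo in ann.geometry:
                writer.writerow([geo["entry_id"], geo["h_chain"], geo["l_chain"],
                                 geo["elbow_deg"], geo["ch1_cl_deg"],
                                 geo["n_ch1_cl_contacts"], geo["buried_area"],
                                 geo.get("n_disulfides", 0)])

    records = [rec for ann in result.annotated for rec in ann.search_records]
    result.index = build_index(records)
    index_path = out_dir / "index.json"
    with open(index_path, "w") as fh:
        json.dump([{k: v for k, v in dataclasses.asdict(rec).items()
                    if k != "ch1_cl"} for rec in result.index.entries],
                  fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result
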