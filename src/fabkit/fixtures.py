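"""Deterministic synthetic fixtures for offline testing of every module.

The generators emulate the *shapes* of real data -- IMGT-gapped germline
sets, Fab-like structures, paired-repertoire tables, mutational-scan score
tables -- with fully known ground truth, written alongside each fixture as
a JSON sidecar.  Structures are Calpha-trace idealisations (helical domain
curves placed as rigid bodies) with planted dyad geometry, not physically
realistic folds: sufficient for every geometric contract in this package,
but not a substitute for experimental structures.

Everything is a pure function of the :class:`FixtureSpec` seed; identical
specs produce byte-identical files (text formats, fixed 3-decimal floats).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ArgumentError
from .refdata import (GAP, ReferenceAllele, ReferenceSet, gapped_position_map,
                      write_gapped_fasta, write_sidecar)
from .structgeom import Atom, ChainCoordinates, ParsedStructure, Residue

AA20 = "ACDEFGHIKLMNPQRSTVWY"

SPECIES_POOL = [
    ("Homo sapiens", "hs"),
    ("Mus musculus", "mm"),
    ("Oryctolagus cuniculus", "oc"),
    ("Rattus norvegicus", "rn"),
]

#: gene, gene_class, chain_class, domain_label
GENE_ROSTER = [
    ("IGHV1-1", "V", "H", "V"),
    ("IGKV1-1", "V", "K", "V"),
    ("IGHG1", "C", "H", "CH1"),
    ("IGHG1", "C", "H", "CH2"),
    ("IGHG1", "C", "H", "CH3"),
    ("IGKC", "C", "K", "CL"),
]
EXTENDED_ROSTER = GENE_ROSTER + [
    ("IGHA1", "C", "H", "CH1"),
    ("IGLV2-1", "V", "L", "V"),
    ("IGLC1", "C", "L", "CL"),
]

DEFAULT_DOMAIN_LENGTHS = {"V": 100, "CH1": 95, "CL": 95, "CH2": 100, "CH3": 100}
N_GAP_COLUMNS = 6


@dataclass
class FixtureSpec:
    """Parameters shared by all fixture generators."""

    seed: int
    n_species: int = 2
    divergence: float = 0.15
    domain_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_LENGTHS))
    geometry: dict[str, float] = field(default_factory=lambda: {
        "elbow_deg": 120.0, "ch1_cl_deg": 150.0, "v_dyad_deg": 165.0})
    unresolved_spans: list[tuple[str, int, int]] = field(default_factory=list)
    extended_roster: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.5):
            raise ArgumentError("divergence must be in [0, 0.5]")
        for label, n in self.domain_lengths.items():
            if n < 20:
                raise ArgumentError(f"domain length for {label} must be >= 20")
        if self.n_species < 1 or self.n_species > len(SPECIES_POOL):
            raise ArgumentError(f"n_species must be in 1..{len(SPECIES_POOL)}")


# ---------------------------------------------------------------------------
# reference sets

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            choices = [c for c in AA20 if c != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _insert_gaps(seq: str, gap_cols: list[int]) -> str:
    """Place the sequence on a gapped scaffold with '.' at ``gap_cols`` (1-based)."""
    width = len(seq) + len(gap_cols)
    gap_set = set(gap_cols)
    out = []
    it = iter(seq)
    for col in range(1, width + 1):
        out.append(GAP if col in gap_set else next(it))
    return "".join(out)


def build_reference_set(spec: FixtureSpec) -> ReferenceSet:
    """Synthesise a cross-species germline reference set in memory.

    Species 0 carries the ancestral sequences; every further species is an
    independently substituted copy at rate ``spec.divergence``, so
    homologous alleles of species 0 and species k share ~(1 - divergence)
    identity.  Gap columns are fixed per domain label, so gapped widths
    agree within each alignment set.
    """
    rng = np.random.default_rng(spec.seed)
    roster = EXTENDED_ROSTER if spec.extended_roster else GENE_ROSTER
    labels_in_order = sorted({d for _, _, _, d in roster})
    # CH1 and CL share one numbering scaffold (one C-domain scheme), exactly
    # as all V domains share theirs -- label correspondence across the
    # CH1-CL pair is what makes cross-entry comparison possible.
    scheme = {"CH1": "Cdom", "CL": "Cdom"}
    if spec.domain_lengths["CH1"] != spec.domain_lengths["CL"]:
        raise ArgumentError("CH1 and CL share a numbering scheme and must have "
                            "equal lengths")
    gap_cols_by_scheme: dict[str, list[int]] = {}
    gap_cols: dict[str, list[int]] = {}
    for label in labels_in_order:
        key = scheme.get(label, label)
        if key not in gap_cols_by_scheme:
            n = spec.domain_lengths[label]
            width = n + N_GAP_COLUMNS
            # never a gap in the first/last column, keeps round-trips tidy
            cols = rng.choice(np.arange(2, width), size=N_GAP_COLUMNS,
                              replace=False)
            gap_cols_by_scheme[key] = sorted(int(c) for c in cols)
        gap_cols[label] = gap_cols_by_scheme[key]
    species = SPECIES_POOL[:spec.n_species]
    alleles: list[ReferenceAllele] = []
    for gene, gene_class, chain_class, domain_label in roster:
        ancestor = _random_seq(rng, spec.domain_lengths[domain_label])
        for k, (sp_name, sp_code) in enumerate(species):
            seq = ancestor if k == 0 else _mutate(rng, ancestor, spec.divergence)
            alleles.append(ReferenceAllele(
                allele_id=f"{gene}*01_{sp_code}_{domain_label}",
                species=sp_name, gene_class=gene_class, chain_class=chain_class,
                domain_label=domain_label,
                gapped_seq=_insert_gaps(seq, gap_cols[domain_label])))
    return ReferenceSet(alleles)


def make_reference_fixture(spec: FixtureSpec, out_dir: str | Path
                           ) -> tuple[Path, Path, ReferenceSet]:
    """Write the synthetic reference set as gapped FASTA plus TSV sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refset = build_reference_set(spec)
    fasta = write_gapped_fasta(refset, out_dir / "references.fasta")
    sidecar = write_sidecar(refset, out_dir / "references.fasta.meta.tsv")
    return fasta, sidecar, refset


def _species_allele(refset: ReferenceSet, gene: str, domain: str, code: str
                    ) -> ReferenceAllele:
    return refset.get(f"{gene}*01_{code}_{domain}")


# ---------------------------------------------------------------------------
# structures

def _domain_curve(n: int, origin: np.ndarray, phase: float = 0.0) -> np.ndarray:
    """Compact helical Calpha curve: non-collinear for any >= 3 residues."""
    t = np.arange(n, dtype=float)
    radius, turn, pitch = 8.0, 0.7, 1.2
    return origin + np.stack([radius * np.cos(turn * t + phase),
                              radius * np.sin(turn * t + phase),
                              pitch * t], axis=1)


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * math.radians(angle_deg)).as_matrix()


def write_mmcif(path: str | Path, entry_id: str,
                chains: list[tuple[str, str, list[Residue]]]) -> Path:
    """Write a minimal polymer mmCIF (3-decimal coordinates, deterministic).

    ``chains`` holds (chain_id, seqres_seq, resolved residues).
    """
    three = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
             "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
             "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
             "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
             "X": "UNK"}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"data_{entry_id}", f"_entry.id {entry_id}", "loop_",
             "_entity.id", "_entity.type"]
    for i, _ in enumerate(chains, start=1):
        lines.append(f"{i} polymer")
    lines += ["loop_", "_entity_poly.entity_id", "_entity_poly.type",
              "_entity_poly.pdbx_strand_id"]
    for i, (cid, _, _) in enumerate(chains, start=1):
        lines.append(f"{i} polypeptide(L) {cid}")
    lines += ["loop_", "_entity_poly_seq.entity_id", "_entity_poly_seq.num",
              "_entity_poly_seq.mon_id"]
    for i, (_, seqres, _) in enumerate(chains, start=1):
        for num, aa in enumerate(seqres, start=1):
            lines.append(f"{i} {num} {three[aa]}")
    lines += ["loop_", "_atom_site.group_PDB", "_atom_site.id",
              "_atom_site.type_symbol", "_atom_site.label_atom_id",
              "_atom_site.label_alt_id", "_atom_site.label_comp_id",
              "_atom_site.label_asym_id", "_atom_site.label_entity_id",
              "_atom_site.label_seq_id", "_atom_site.pdbx_PDB_ins_code",
              "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
              "_atom_site.occupancy", "_atom_site.B_iso_or_equiv",
              "_atom_site.auth_seq_id", "_atom_site.auth_asym_id",
              "_atom_site.pdbx_PDB_model_num"]
    serial = 0
    asym_ids = "ABCDEFGHIJ"
    for i, (cid, seqres, residues) in enumerate(chains, start=1):
        asym = asym_ids[i - 1]
        for res in residues:
            comp = three[res.amino_acid]
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM {serial} {atom.element} {atom.name} . {comp} {asym} "
                    f"{i} {res.seqres_index} ? {x:.3f} {y:.3f} {z:.3f} "
                    f"1.00 0.00 {res.seqres_index} {cid} 1")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def make_structure_fixture(spec: FixtureSpec, annotation: dict | None,
                           out_dir: str | Path) -> tuple[Path, Path]:
    """Build an idealised Fab-like structure with planted geometry.

    The light-chain V domain is a rigid copy of the heavy-chain V domain
    rotated by ``v_dyad_deg`` about the V-module dyad axis; CL is a copy
    of CH1 rotated by ``ch1_cl_deg`` about the C-module dyad axis, which
    is tilted from the V axis by exactly the requested elbow angle.  The
    ground-truth sidecar records the planted angles, the brute-force
    CH1 x CL contact list under the 8 A default cutoff, the planted
    disulfides, and the coverage class implied by the domain layout and
    unresolved spans.
    """
    ann = {"entry_id": "FX0001", "species_code": "hs",
           "heavy_domains": ["V", "CH1"], "light_domains": ["V", "CL"],
           "disulfides": True, "unresolved": list(spec.unresolved_spans),
           "provided_species": None, **(annotation or {})}
    geom = spec.geometry
    elbow = float(ann.get("elbow_deg", geom["elbow_deg"]))
    theta_c = float(ann.get("ch1_cl_deg", geom["ch1_cl_deg"]))
    theta_v = float(ann.get("v_dyad_deg", geom["v_dyad_deg"]))
    for name, val in (("v_dyad_deg", theta_v), ("ch1_cl_deg", theta_c)):
        if not (0.0 < val < 180.0):
            raise ArgumentError(f"{name} must lie strictly in (0, 180); "
                                f"got {val} (axis sign otherwise undefined)")
    if not (0.0 <= elbow <= 180.0):
        raise ArgumentError("elbow_deg must lie in [0, 180]")

    refset = build_reference_set(spec)
    code = ann["species_code"]
    nV = spec.domain_lengths["V"]
    h_parts = {"V": _species_allele(refset, "IGHV1-1", "V", code).ungapped_seq}
    for d in ann["heavy_domains"]:
        if d != "V":
            h_parts[d] = _species_allele(refset, "IGHG1", d, code).ungapped_seq
    l_parts = {"V": _species_allele(refset, "IGKV1-1", "V", code).ungapped_seq,
               "CL": _species_allele(refset, "IGKC", "CL", code).ungapped_seq}

    axis_v = np.array([0.0, 0.0, 1.0])
    axis_c = np.array([math.sin(math.radians(elbow)), 0.0,
                       math.cos(math.radians(elbow))])

    # V module: VL is a rotated rigid copy of VH
    vh = _domain_curve(nV, np.zeros(3))
    cen_v = vh.mean(axis=0)
    vl = (vh - cen_v) @ _rotation_matrix(axis_v, theta_v).T + cen_v \
        + np.array([14.0, 4.0, 0.0])
    # C module: CL is a rotated rigid copy of CH1, dyad tilted by the elbow
    nC = spec.domain_lengths["CH1"]
    ch1 = _domain_curve(nC, np.array([40.0, 0.0, 10.0]), phase=1.0)
    cen_c = ch1.mean(axis=0)
    cl = (ch1 - cen_c) @ _rotation_matrix(axis_c, theta_c).T + cen_c \
        + np.array([12.0, 5.0, 0.0])

    coords_h: dict[str, np.ndarray] = {"V": vh, "CH1": ch1}
    offset = 80.0
    for d in ("CH2", "CH3"):
        if d in h_parts:
            coords_h[d] = _domain_curve(spec.domain_lengths[d],
                                        np.array([offset, 0.0, 0.0]), phase=2.0)
            offset += 50.0
    coords_l = {"V": vl, "CL": cl}

    # assemble chains, planting cysteine pairs before writing
    def _assemble(parts: dict[str, str], coords: dict[str, np.ndarray],
                  order: list[str]) -> tuple[str, list[tuple[str, int, np.ndarray]]]:
        seq = ""
        placed: list[tuple[str, int, np.ndarray]] = []  # (domain, seqres_idx, ca)
        for d in order:
            for i, aa in enumerate(parts[d]):
                placed.append((d, len(seq) + i + 1, coords[d][i]))
            seq += parts[d]
        return seq, placed

    h_seq, h_placed = _assemble(h_parts, coords_h, ann["heavy_domains"])
    l_seq, l_placed = _assemble(l_parts, coords_l, ann["light_domains"])

    disulfides: list[dict] = []
    cys_positions: dict[str, set[int]] = {"H": set(), "L": set()}
    if ann["disulfides"]:
        # two intra-domain pairs (one per V domain) and one inter-chain pair
        pairs = [("H", 5, "H", 12, "intra"), ("L", 5, "L", 12, "intra"),
                 ("H", nV + nC, "L", nV + spec.domain_lengths["CL"], "inter")]
        for ca_chain, ra, cb_chain, rb, kind in pairs:
            disulfides.append({"chain_a": ca_chain, "res_a": ra,
                               "chain_b": cb_chain, "res_b": rb, "kind": kind})
            cys_positions[ca_chain].add(ra)
            cys_positions[cb_chain].add(rb)

    def _with_cys(seq: str, positions: set[int]) -> str:
        out = list(seq)
        for p in positions:
            out[p - 1] = "C"
        return "".join(out)

    h_seq = _with_cys(h_seq, cys_positions["H"])
    l_seq = _with_cys(l_seq, cys_positions["L"])

    unresolved = {(c, i) for (c, s, e) in ann["unresolved"] for i in range(s, e + 1)}

    def _residues(chain_id: str, seq: str,
                  placed: list[tuple[str, int, np.ndarray]]) -> list[Residue]:
        out = []
        for domain, idx, ca in placed:
            if (chain_id, idx) in unresolved:
                continue
            out.append(Residue(seqres_index=idx, amino_acid=seq[idx - 1],
                               atoms=[Atom("CA", "C", tuple(round(v, 3) for v in ca))]))
        return out

    h_res = _residues("H", h_seq, h_placed)
    l_res = _residues("L", l_seq, l_placed)

    # SG atoms for planted disulfides (2.05 A apart at the pair midpoint)
    res_by_key = {("H", r.seqres_index): r for r in h_res}
    res_by_key.update({("L", r.seqres_index): r for r in l_res})
    for k, bond in enumerate(disulfides):
        a = res_by_key.get((bond["chain_a"], bond["res_a"]))
        b = res_by_key.get((bond["chain_b"], bond["res_b"]))
        if a is None or b is None:
            continue  # unresolved span swallowed a partner
        pa, pb = np.array(a.ca), np.array(b.ca)
        u = pb - pa
        u = u / np.linalg.norm(u)
        mid = (pa + pb) / 2.0
        a.atoms.append(Atom("SG", "S", tuple(round(v, 3) for v in mid - 1.025 * u)))
        b.atoms.append(Atom("SG", "S", tuple(round(v, 3) for v in mid + 1.025 * u)))

    # ground truth: coverage class
    resolved_domains = {d for d, idx, _ in h_placed if ("H", idx) not in unresolved}
    resolved_domains |= {d for d, idx, _ in l_placed if ("L", idx) not in unresolved}
    if resolved_domains & {"CH2", "CH3", "CH4"}:
        coverage = "full"
    elif "V" in resolved_domains and resolved_domains & {"CH1", "CL"}:
        coverage = "Fab"
    else:
        coverage = "other"

    # ground truth: brute-force CH1 x CL Calpha contacts under 8 A,
    # keyed by the alleles' own gapped column labels
    ch1_cols = gapped_position_map(_species_allele(refset, "IGHG1", "CH1", code))
    cl_cols = gapped_position_map(_species_allele(refset, "IGKC", "CL", code))
    contacts = []
    for i in range(nC):
        h_idx = nV + i + 1
        if ("H", h_idx) in unresolved:
            continue
        for j in range(spec.domain_lengths["CL"]):
            l_idx = nV + j + 1
            if ("L", l_idx) in unresolved:
                continue
            d = float(np.linalg.norm(np.array(res_by_key[("H", h_idx)].ca)
                                     - np.array(res_by_key[("L", l_idx)].ca)))
            if d <= 8.0:
                contacts.append([str(ch1_cols[i + 1]), str(cl_cols[j + 1]),
                                 round(d, 3)])

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cif = write_mmcif(out_dir / f"{ann['entry_id']}.cif", ann["entry_id"],
                      [("H", h_seq, h_res), ("L", l_seq, l_res)])
    truth = {
        "entry_id": ann["entry_id"], "elbow_deg": elbow, "ch1_cl_deg": theta_c,
        "v_dyad_deg": theta_v, "coverage_class": coverage,
        "species": [s for s, c in SPECIES_POOL if c == code][0],
        "disulfides": disulfides, "ch1_cl_contacts": contacts,
        "heavy_seq": h_seq, "light_seq": l_seq,
        "unresolved": [list(t) for t in ann["unresolved"]],
    }
    truth_path = out_dir / f"{ann['entry_id']}.truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return cif, truth_path


def load_structure_fixture(cif_path: str | Path) -> ParsedStructure:
    from .structgeom import read_structure
    return read_structure(cif_path, format="mmcif")


# ---------------------------------------------------------------------------
# repertoires

def make_repertoire_fixture(spec: FixtureSpec, dialect: str, out_dir: str | Path,
                            n_cells: int = 10, n_unpaired: int = 2,
                            mutation_rate: float = 0.05) -> tuple[Path, Path]:
    """Write a paired-chain repertoire in the requested dialect.

    Cell sequences are V+C chains derived from the species-0 references
    with a per-residue substitution load of ``mutation_rate``; the last
    ``n_unpaired`` cells lack their light chain.  The logical content is a
    function of the seed only, so every dialect of the same spec parses to
    the same query list.
    """
    if dialect not in ("airr_tsv", "csv", "tenx_contig_csv"):
        raise ValueError(f"unknown repertoire dialect {dialect!r}")
    rng = np.random.default_rng(spec.seed)
    refset = build_reference_set(spec)
    h_base = (_species_allele(refset, "IGHV1-1", "V", "hs").ungapped_seq
              + _species_allele(refset, "IGHG1", "CH1", "hs").ungapped_seq)
    l_base = (_species_allele(refset, "IGKV1-1", "V", "hs").ungapped_seq
              + _species_allele(refset, "IGKC", "CL", "hs").ungapped_seq)
    cells = []
    for i in range(n_cells):
        cell = {"cell_id": f"cell{i + 1:03d}",
                "heavy": _mutate(rng, h_base, mutation_rate),
                "light": _mutate(rng, l_base, mutation_rate),
                "paired": i < n_cells - n_unpaired}
        if not cell["paired"]:
            cell["light"] = None
        cells.append(cell)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"airr_tsv": "tsv", "csv": "csv", "tenx_contig_csv": "csv"}[dialect]
    data_path = out_dir / f"repertoire_{dialect}.{ext}"
    if dialect == "tenx_contig_csv":
        header = ["contig_id", "barcode", "chain", "sequence_aa"]
        sep = ","
    else:
        header = ["sequence_id", "cell_id", "locus", "sequence_aa"]
        sep = "\t" if dialect == "airr_tsv" else ","
    lines = [sep.join(header)]
    for cell in cells:
        rows = [(f"{cell['cell_id']}_H", cell["cell_id"], "IGH", cell["heavy"])]
        if cell["light"] is not None:
            rows.append((f"{cell['cell_id']}_L", cell["cell_id"], "IGK", cell["light"]))
        for row in rows:
            lines.append(sep.join(row))
    with open(data_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    truth_path = out_dir / "repertoire.truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"cells": cells, "mutation_rate": mutation_rate}, fh,
                  indent=1, sort_keys=True)
        fh.write("\n")
    return data_path, truth_path


# ---------------------------------------------------------------------------
# mutational-scan scores

def make_score_fixture(spec: FixtureSpec, out_dir: str | Path,
                       n_positions: int = 50, n_planted: int = 3,
                       shift: float = 2.0, sigma: float = 0.5,
                       scorer_tag: str = "rosetta_pmut"
                       ) -> tuple[Path, Path, Path, Path]:
    """Write raw score CSVs for three pseudo-isotypes sharing a V region.

    Isotypes B and "control" are independent Gaussian noise (the two
    same-isotype structures); isotype A is independent noise plus a
    ``shift`` added to every non-WT substitution at ``n_planted`` randomly
    chosen positions -- the planted isotype-sensitive sites listed in the
    truth sidecar.
    """
    rng = np.random.default_rng(spec.seed)
    positions = [str(i + 1) for i in range(n_positions)]
    wt = [AA20[rng.integers(20)] for _ in range(n_positions)]
    planted = sorted(rng.choice(n_positions, size=n_planted, replace=False).tolist())
    planted_labels = [positions[i] for i in planted]

    def _table(plant: bool) -> list[tuple[str, str, str, float]]:
        rows = []
        for i, pos in enumerate(positions):
            for aa in AA20:
                val = float(rng.normal(0.0, sigma))
                if plant and i in planted and aa != wt[i]:
                    val += shift
                rows.append((pos, wt[i], aa, val))
        return rows

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _write(name: str, rows) -> Path:
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write("position_label,wt_aa,mut_aa,score\n")
            for pos, w, aa, val in rows:
                fh.write(f"{pos},{w},{aa},{val:.6f}\n")
        return path

    # draw order fixed: iso_b, control, iso_a
    p_b = _write("scores_iso_b.csv", _table(False))
    p_ctrl = _write("scores_control.csv", _table(False))
    p_a = _write("scores_iso_a.csv", _table(True))
    truth_path = out_dir / "scores.truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"planted_positions": planted_labels, "shift": shift,
                   "sigma": sigma, "scorer_tag": scorer_tag}, fh,
                  indent=1, sort_keys=True)
        fh.write("\n")
    return p_a, p_b, p_ctrl, truth_path
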