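"""Germline reference allele sets in IMGT-gapped form.

A reference set holds one entry per germline allele and per constant domain
(V, CH1, CH2, CH3, CH4, CL, hinge).  Sequences are stored both gapped --
with "." at the fixed alignment columns of the IMGT scheme -- and ungapped.
The gapped columns are what downstream numbering transfer uses: a query
residue aligned to reference residue *r* inherits the alignment column of
*r* as its position label.

All sequence coordinates in this package are 1-based, matching the IMGT
convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError

GAP = "."
#: "-" is accepted on input as a gap synonym and normalised to ".".
GAP_SYNONYMS = ("-",)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
VALID_GENE_CLASSES = {"V", "C"}
VALID_CHAIN_CLASSES = {"H", "K", "L"}
VALID_DOMAIN_LABELS = {"V", "CH1", "CH2", "CH3", "CH4", "CL", "hinge", "none"}

#: Domains excluded from numbering transfer.  IMGT C-domain numbering does
#: not cover the hinge, so hinge reference entries only serve detection.
NON_NUMBERED_DOMAINS = {"hinge"}


@dataclass(frozen=True)
class ReferenceAllele:
    """One germline V or C allele restricted to a single domain."""

    allele_id: str
    species: str
    gene_class: str   # "V" or "C"
    chain_class: str  # "H", "K" or "L"
    domain_label: str
    gapped_seq: str

    @property
    def ungapped_seq(self) -> str:
        return self.gapped_seq.replace(GAP, "")

    @property
    def gene(self) -> str:
        """Gene-level prefix of the allele id (text before '*')."""
        return self.allele_id.split("*")[0]

    def validate(self) -> None:
        if self.gene_class not in VALID_GENE_CLASSES:
            raise ValidationError(
                f"{self.allele_id}: gene_class {self.gene_class!r} not in {sorted(VALID_GENE_CLASSES)}")
        if self.chain_class not in VALID_CHAIN_CLASSES:
            raise ValidationError(
                f"{self.allele_id}: chain_class {self.chain_class!r} not in {sorted(VALID_CHAIN_CLASSES)}")
        if self.domain_label not in VALID_DOMAIN_LABELS:
            raise ValidationError(
                f"{self.allele_id}: unknown domain_label {self.domain_label!r}")
        bad = set(self.gapped_seq) - set(AA20) - {GAP}
        if bad:
            raise ValidationError(
                f"{self.allele_id}: unknown amino-acid letter(s) {sorted(bad)}")
        if len(self.ungapped_seq) < 1:
            raise ValidationError(f"{self.allele_id}: empty ungapped sequence")


@dataclass
class ReferenceSet:
    """Validated, indexed collection of reference alleles."""

    alleles: list[ReferenceAllele] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for a in self.alleles:
            a.validate()
            if a.allele_id in seen:
                raise ValidationError(f"duplicate allele_id {a.allele_id!r}")
            seen.add(a.allele_id)
        # constant gapped width within each (gene_class, domain_label) set
        widths: dict[tuple[str, str], dict[str, int]] = {}
        for a in self.alleles:
            widths.setdefault((a.gene_class, a.domain_label), {})[a.allele_id] = len(a.gapped_seq)
        for key, per_allele in widths.items():
            if len(set(per_allele.values())) > 1:
                offenders = ", ".join(f"{aid}={w}" for aid, w in sorted(per_allele.items()))
                raise ValidationError(
                    f"inconsistent gapped lengths in alignment set {key}: {offenders}")

    @property
    def alignment_width(self) -> dict[tuple[str, str], int]:
        return {(a.gene_class, a.domain_label): len(a.gapped_seq) for a in self.alleles}

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    def get(self, allele_id: str) -> ReferenceAllele:
        for a in self.alleles:
            if a.allele_id == allele_id:
                return a
        raise KeyError(allele_id)

    def by_domain(self, domain_label: str) -> list[ReferenceAllele]:
        return [a for a in self.alleles if a.domain_label == domain_label]

    def searchable(self) -> list[ReferenceAllele]:
        """Alleles usable as domain-detection targets (hinge excluded)."""
        return [a for a in self.alleles if a.domain_label not in NON_NUMBERED_DOMAINS]

    def has_full_pipeline_support(self) -> bool:
        classes = {a.gene_class for a in self.alleles}
        return {"V", "C"} <= classes


def _normalise_gaps(seq: str) -> str:
    for syn in GAP_SYNONYMS:
        seq = seq.replace(syn, GAP)
    return seq


def _read_fasta(path: Path) -> list[tuple[str, str, int]]:
    """Minimal strict FASTA reader returning (header, seq, line_no)."""
    records: list[tuple[str, str, int]] = []
    header: str | None = None
    seq_parts: list[str] = []
    header_line = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(seq_parts), header_line))
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {line_no}")
                seq_parts = []
                header_line = line_no
            else:
                if header is None:
                    raise ParseError(
                        f"{path}: sequence data before first header at line {line_no}")
                seq_parts.append(line)
    if header is not None:
        records.append((header, "".join(seq_parts), header_line))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _read_sidecar(path: Path) -> dict[str, dict[str, str]]:
    required = ["allele_id", "species", "gene_class", "chain_class", "domain_label"]
    table: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: sidecar missing column(s) {missing}")
        for row in reader:
            table[row["allele_id"]] = row
    return table


def load_gapped_fasta(path: str | Path,
                      metadata_mode: str = "header_fields",
                      sidecar: str | Path | None = None) -> ReferenceSet:
    """Load a gapped reference FASTA into a validated :class:`ReferenceSet`.

    ``metadata_mode="header_fields"`` expects pipe-delimited headers
    ``allele_id|species|gene_class|chain_class|domain_label`` (the shape of
    IMGT reference downloads).  ``metadata_mode="sidecar_table"`` takes the
    allele_id from the header and the remaining metadata from a TSV sidecar
    (default: ``<path>.meta.tsv``).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"reference FASTA not found: {path}")
    if metadata_mode not in ("header_fields", "sidecar_table"):
        raise ValueError(f"unknown metadata_mode {metadata_mode!r}")

    records = _read_fasta(path)
    meta: dict[str, dict[str, str]] | None = None
    if metadata_mode == "sidecar_table":
        sidecar_path = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".meta.tsv")
        if not sidecar_path.exists():
            raise ParseError(f"sidecar table not found: {sidecar_path}")
        meta = _read_sidecar(sidecar_path)

    alleles: list[ReferenceAllele] = []
    for header, seq, line_no in records:
        seq = _normalise_gaps(seq.upper())
        if metadata_mode == "header_fields":
            fields = [f.strip() for f in header.split("|")]
            if len(fields) < 5:
                raise ParseError(
                    f"{path}: header at line {line_no} has {len(fields)} pipe-delimited "
                    f"fields, expected allele_id|species|gene_class|chain_class|domain_label")
            allele_id, species, gene_class, chain_class, domain_label = fields[:5]
        else:
            allele_id = header.split("|")[0].split()[0]
            assert meta is not None
            if allele_id not in meta:
                raise ParseError(f"{path}: allele {allele_id!r} absent from sidecar table")
            row = meta[allele_id]
            species = row["species"]
            gene_class = row["gene_class"]
            chain_class = row["chain_class"]
            domain_label = row["domain_label"]
        alleles.append(ReferenceAllele(
            allele_id=allele_id, species=species, gene_class=gene_class,
            chain_class=chain_class, domain_label=domain_label, gapped_seq=seq))
    return ReferenceSet(alleles)


def write_gapped_fasta(refset: ReferenceSet | Iterable[ReferenceAllele],
                       path: str | Path, width: int = 60) -> Path:
    """Write a reference set with pipe-delimited metadata headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a in refset:
            fh.write(f">{a.allele_id}|{a.species}|{a.gene_class}|{a.chain_class}|{a.domain_label}\n")
            for i in range(0, len(a.gapped_seq), width):
                fh.write(a.gapped_seq[i:i + width] + "\n")
    return path


def write_sidecar(refset: ReferenceSet | Iterable[ReferenceAllele], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["allele_id", "species", "gene_class", "chain_class", "domain_label"])
        for a in refset:
            writer.writerow([a.allele_id, a.species, a.gene_class, a.chain_class, a.domain_label])
    return path


def gapped_position_map(allele: ReferenceAllele) -> dict[int, int]:
    """Map ungapped residue index (1-based) to gapped column index (1-based).

    The map is strictly increasing and has one entry per ungapped residue;
    composing it with gap removal reconstructs the gapped layout.
    """
    mapping: dict[int, int] = {}
    resi = 0
    for col, ch in enumerate(allele.gapped_seq, start=1):
        if ch != GAP:
            resi += 1
            mapping[resi] = col
    return mapping
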