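"""Chain- and structure-level annotation built on top of domain hits.

This layer turns per-domain germline hits into the annotations a curated
antibody-structure table carries: a consolidated species call with an
override margin against the depositor-provided species, engineered-format
flags (chimeric / humanized), the isotype or light-chain type, and a
structural-coverage class (Fab / full / other) judged on the residues that
actually have coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ArgumentError, DataInconsistencyError
from .numbering import DomainHit, align_pair, detect_domains
from .refdata import ReferenceSet

#: Percentage-point identity margin a foreign-species hit must exceed over
#: the best provided-species hit before the provided species is overridden.
DEFAULT_OVERRIDE_MARGIN = 8.0

C_DOMAINS = ("CH1", "CH2", "CH3", "CH4", "CL")
FC_DOMAINS = ("CH2", "CH3", "CH4")

_ISOTYPE_BY_GENE = {
    "IGHG1": "IgG1", "IGHG2": "IgG2", "IGHG3": "IgG3", "IGHG4": "IgG4",
    "IGHA1": "IgA1", "IGHA2": "IgA2",
    "IGHM": "IgM", "IGHD": "IgD", "IGHE": "IgE",
    "IGKC": "kappa",
}


@dataclass
class ChainAnnotation:
    chain_id: str
    chain_class: str  # H / K / L / ambiguous
    per_domain_species: dict[str, tuple[str, float]] = field(default_factory=dict)
    consolidated_species: str = ""
    engineered_flag: str = "none"  # none / chimeric / humanized / unresolved
    isotype_or_lctype: str = ""
    c_allele: str = ""
    hits: list[DomainHit] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class StructureRecord:
    entry_id: str
    chains: list[ChainAnnotation] = field(default_factory=list)
    coverage_class: str = "other"  # Fab / full / other
    seqres_seq: dict[str, str] = field(default_factory=dict)
    atom_seq: dict[str, str] = field(default_factory=dict)
    provided_species: str = ""


def species_identity_table(query_span: str, refs: ReferenceSet, domain_label: str
                           ) -> dict[str, tuple[float, str]]:
    """Best local-alignment identity per species for one domain span.

    Returns ``{species: (percent_identity, allele_id)}`` over all reference
    alleles carrying ``domain_label``.
    """
    table: dict[str, tuple[float, str]] = {}
    for allele in refs.by_domain(domain_label):
        ali = align_pair(query_span, allele.ungapped_seq, mode="local")
        cur = table.get(allele.species)
        if cur is None or (ali.percent_identity, allele.allele_id) > cur:
            table[allele.species] = (ali.percent_identity, allele.allele_id)
    return table


def consolidate_species(per_domain_hits: dict[str, dict[str, float]],
                        provided_species: str,
                        override_margin: float = DEFAULT_OVERRIDE_MARGIN
                        ) -> tuple[str, dict[str, tuple[str, float]]]:
    """Resolve a species per domain, then consolidate across domains.

    ``per_domain_hits`` maps domain_label -> {species: best identity}.  Per
    domain the provided species is kept unless the best foreign hit beats
    the best provided-species hit by strictly more than ``override_margin``
    percentage points; if the provided species has no hit at all the best
    hit wins unconditionally.  The consolidated value is the single shared
    species, or a slash-joined composite when domains disagree (the
    chimera case, see :func:`flag_engineered`).
    """
    if not per_domain_hits:
        raise ArgumentError("consolidate_species requires at least one domain")
    table: dict[str, tuple[str, float]] = {}
    for domain, by_species in per_domain_hits.items():
        if not by_species:
            raise ArgumentError(f"domain {domain!r} has no species hits")
        best_species, best_ident = max(by_species.items(), key=lambda kv: (kv[1], kv[0]))
        if provided_species in by_species:
            provided_ident = by_species[provided_species]
            if best_species != provided_species and best_ident - provided_ident > override_margin:
                table[domain] = (best_species, best_ident)
            else:
                table[domain] = (provided_species, provided_ident)
        else:
            # provided species absent from the references: best hit wins
            table[domain] = (best_species, best_ident)
    distinct = []
    for domain in sorted(table, key=_domain_order):
        sp = table[domain][0]
        if sp not in distinct:
            distinct.append(sp)
    consolidated = distinct[0] if len(distinct) == 1 else "/".join(distinct)
    return consolidated, table


def _domain_order(label: str) -> int:
    order = ["V", "CH1", "CL", "hinge", "CH2", "CH3", "CH4"]
    return order.index(label) if label in order else len(order)


def flag_engineered(domain_species: dict[str, str],
                    v_mixed_evidence: bool = False) -> str:
    """Classify the engineered format of a chain (or an H-L pair).

    All domains from one species -> "none"; V and C regions from different
    species -> "chimeric"; same species throughout but with mixed top-hit
    evidence inside the V domain (CDR-grafting signature) -> "humanized"
    (heuristic -- callers should surface the accompanying confidence note);
    anything else -> "unresolved".
    """
    v_species = {s for d, s in domain_species.items() if d == "V"}
    c_species = {s for d, s in domain_species.items() if d in C_DOMAINS}
    if not v_species or not c_species:
        raise ArgumentError("flag_engineered requires both a V and a C verdict")
    if len(v_species) == 1 and v_species == c_species:
        return "humanized" if v_mixed_evidence else "none"
    if len(v_species) == 1 and len(c_species) == 1:
        return "chimeric"
    return "unresolved"


def humanized_evidence(v_span: str, refs: ReferenceSet, margin: float = 2.0
                       ) -> bool:
    """Mixed-species V evidence: top-2 species identities within ``margin``.

    A grafted V region resembles two species' germlines almost equally
    well; this is the (heuristic) trigger for the "humanized" flag.
    """
    table = species_identity_table(v_span, refs, "V")
    if len(table) < 2:
        return False
    idents = sorted((ident for ident, _ in table.values()), reverse=True)
    return (idents[0] - idents[1]) <= margin


def assign_isotype(c_hits: list[DomainHit]) -> tuple[str, str]:
    """Isotype / light-chain type from the best-identity C-domain hit.

    Ties on identity break by alignment score, then allele_id.  Returns
    ``(isotype_or_lctype, c_allele_id)``.
    """
    c_hits = [h for h in c_hits if h.allele.gene_class == "C"]
    if not c_hits:
        raise ArgumentError("V-only chain: no C-domain hit to assign an isotype from")
    best = min(c_hits, key=lambda h: (-h.percent_identity, -h.alignment_score,
                                      h.allele.allele_id))
    return isotype_from_allele(best.allele.allele_id), best.allele.allele_id


def isotype_from_allele(allele_id: str) -> str:
    gene = allele_id.split("*")[0]
    if gene in _ISOTYPE_BY_GENE:
        return _ISOTYPE_BY_GENE[gene]
    if gene.startswith("IGLC"):
        return "lambda"
    if gene.startswith("IGKC"):
        return "kappa"
    return gene  # unknown nomenclature: pass the gene through


def classify_coverage(atom_resolved_domains: set[str]) -> str:
    """Fab / full / other from the set of coordinate-resolved domains.

    Any Fc domain (CH2/CH3/CH4) resolved -> "full"; otherwise V together
    with CH1 or CL -> "Fab"; otherwise "other".
    """
    if atom_resolved_domains & set(FC_DOMAINS):
        return "full"
    if "V" in atom_resolved_domains and atom_resolved_domains & {"CH1", "CL"}:
        return "Fab"
    return "other"


def is_subsequence(sub: str, full: str) -> bool:
    it = iter(full)
    return all(ch in it for ch in sub)


def structural_coverage(seqres_seq: str, atom_seq: str, refs: ReferenceSet,
                        min_identity: float = 50.0, min_length: int = 50
                        ) -> dict[str, tuple[int, int, float]]:
    """Per-domain coverage from the ATOM-record sequence.

    Domains are detected on ``atom_seq`` (the residues that truly have
    coordinates), not on the deposited SEQRES.  Returns
    ``{domain_label: (atom_start, atom_end, fraction_resolved)}`` where the
    fraction is resolved residues over the reference's ungapped length.
    """
    if not is_subsequence(atom_seq, seqres_seq):
        raise DataInconsistencyError(
            "atom_seq is not a subsequence of seqres_seq; coordinate records "
            "contain residues absent from the deposited polymer sequence")
    hits = detect_domains(atom_seq, refs, min_identity=min_identity, min_length=min_length)
    out: dict[str, tuple[int, int, float]] = {}
    for h in hits:
        frac = h.length / len(h.allele.ungapped_seq)
        prev = out.get(h.domain_label)
        if prev is None or frac > prev[2]:
            out[h.domain_label] = (h.query_start, h.query_end, frac)
    return out
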