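"""Joint V/C domain detection and IMGT-style numbering by alignment transfer.

An input chain is decomposed into germline-like domains by repeated local
alignment against every reference allele: the best hit is accepted, its
span masked, and the remaining segments searched again until nothing
passes the identity/length thresholds.  Each accepted domain is then
numbered by a global alignment to its best allele -- every query residue
aligned to reference residue *r* inherits the IMGT alignment column of *r*
as its label; residues aligned to a reference gap become lettered
insertions ("112a"), and deleted reference columns simply leave holes.

Scoring follows the BLAST protein defaults: BLOSUM62 with affine gap cost
11 + k for a gap of k residues.  "X" is tolerated and scored 0 against
everything.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import biotite.sequence as bseq
import biotite.sequence.align as balign
import numpy as np

from .errors import ArgumentError
from .refdata import GAP, ReferenceAllele, ReferenceSet, gapped_position_map

#: BLAST protein defaults: gap of length k costs GAP_OPEN + k * GAP_EXTEND.
GAP_OPEN = 11
GAP_EXTEND = 1

#: Domain acceptance defaults (identity in percent, length in residues).
DEFAULT_MIN_IDENTITY = 50.0
DEFAULT_MIN_LENGTH = 50


@functools.lru_cache(maxsize=1)
def _substitution_matrix() -> balign.SubstitutionMatrix:
    """BLOSUM62 with the X row/column zeroed (mismatch-neutral)."""
    std = balign.SubstitutionMatrix.std_protein_matrix()
    alph = std.get_alphabet1()
    scores = std.score_matrix().copy()
    x = alph.encode("X")
    scores[x, :] = 0
    scores[:, x] = 0
    return balign.SubstitutionMatrix(alph, alph, scores)


# biotite charges open + (k-1) * extend for a gap of length k, so BLAST's
# 11/1 ("11 + k") is expressed as open 12, extend 1.
_BIOTITE_GAP = (-(GAP_OPEN + GAP_EXTEND), -GAP_EXTEND)


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment in gapped-string form plus its statistics."""

    query_aligned: str
    ref_aligned: str
    score: float
    percent_identity: float
    query_start: int  # 1-based, inclusive; positions of the aligned query span
    query_end: int
    ref_start: int
    ref_end: int
    trace: np.ndarray  # (n_cols, 2) of 0-based indices, -1 marks a gap


@dataclass(frozen=True)
class DomainHit:
    """One accepted domain on a query chain."""

    query_start: int  # 1-based inclusive
    query_end: int
    allele: ReferenceAllele
    percent_identity: float
    alignment_score: float
    rank: int = 1

    @property
    def domain_label(self) -> str:
        return self.allele.domain_label

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass(frozen=True)
class NumberedDomain:
    """IMGT-style labels for one detected domain."""

    domain_label: str
    residues: tuple[tuple[str, str], ...]  # (imgt_label, amino_acid)

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.residues)


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ArgumentError(f"{name} sequence is empty")
    bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWYX")
    if bad:
        raise ArgumentError(f"{name} sequence contains invalid letter(s) {sorted(bad)}")


def align_pair(query: str, reference: str, mode: str = "local") -> Alignment:
    """Align two amino-acid sequences (BLOSUM62, affine gaps 11/1).

    ``mode="local"`` is Smith-Waterman; ``mode="global_query"`` is strict
    Needleman-Wunsch (terminal gaps penalised), so the whole query is
    aligned end-to-end -- the mode numbering transfer uses.
    percent_identity counts identical columns over the full alignment
    length, gap columns included.
    """
    _check_sequence(query, "query")
    _check_sequence(reference, "reference")
    if mode not in ("local", "global_query"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    q = bseq.ProteinSequence(query)
    r = bseq.ProteinSequence(reference)
    alis = balign.align_optimal(
        q, r, _substitution_matrix(), gap_penalty=_BIOTITE_GAP,
        local=(mode == "local"), terminal_penalty=True, max_number=1)
    ali = alis[0]
    trace = ali.trace
    qa, ra = balign.get_symbols(ali)
    q_sym = "".join(GAP if s is None else s for s in qa)
    r_sym = "".join(GAP if s is None else s for s in ra)
    n_cols = len(trace)
    identities = sum(1 for a, b in zip(q_sym, r_sym) if a == b and a != GAP)
    pid = 100.0 * identities / n_cols if n_cols else 0.0
    q_idx = trace[:, 0][trace[:, 0] >= 0]
    r_idx = trace[:, 1][trace[:, 1] >= 0]
    return Alignment(
        query_aligned=q_sym, ref_aligned=r_sym, score=float(ali.score),
        percent_identity=pid,
        query_start=int(q_idx.min()) + 1 if len(q_idx) else 0,
        query_end=int(q_idx.max()) + 1 if len(q_idx) else 0,
        ref_start=int(r_idx.min()) + 1 if len(r_idx) else 0,
        ref_end=int(r_idx.max()) + 1 if len(r_idx) else 0,
        trace=trace)


def _best_hit_in_segment(segment: str, offset: int, refs: ReferenceSet
                         ) -> tuple[Alignment, ReferenceAllele] | None:
    """Best local hit of any searchable allele inside one query segment.

    Ties broken by higher percent identity, then lexicographic allele_id.
    """
    best: tuple[float, float, str] | None = None
    best_pair: tuple[Alignment, ReferenceAllele] | None = None
    for allele in refs.searchable():
        ali = align_pair(segment, allele.ungapped_seq, mode="local")
        key = (ali.score, ali.percent_identity, allele.allele_id)
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]):
            best = key
            best_pair = (ali, allele)
    return best_pair


def detect_domains(query: str, refs: ReferenceSet,
                   min_identity: float = DEFAULT_MIN_IDENTITY,
                   min_length: int = DEFAULT_MIN_LENGTH) -> list[DomainHit]:
    """Greedy non-overlapping decomposition of a chain into domain hits.

    Repeatedly accepts the best-scoring local hit over all reference
    alleles, masks its span, and re-searches the flanking segments.  Hits
    are returned in query order; an empty list means nothing passed the
    thresholds (not an error).
    """
    _check_sequence(query, "query")
    if len(query) < min_length:
        return []
    # open segments as (start_0based, end_0based_exclusive)
    segments: list[tuple[int, int]] = [(0, len(query))]
    accepted: list[DomainHit] = []
    while segments:
        start, end = segments.pop()
        if end - start < min_length:
            continue
        found = _best_hit_in_segment(query[start:end], start, refs)
        if found is None:
            continue
        ali, allele = found
        span_len = ali.query_end - ali.query_start + 1
        if ali.percent_identity < min_identity or span_len < min_length or ali.score <= 0:
            continue
        q_start = start + ali.query_start  # back to 1-based full-query coords
        q_end = start + ali.query_end
        accepted.append(DomainHit(
            query_start=q_start, query_end=q_end, allele=allele,
            percent_identity=ali.percent_identity, alignment_score=ali.score))
        segments.append((start, q_start - 1))
        segments.append((q_end, end))
    accepted.sort(key=lambda h: h.query_start)
    return [DomainHit(h.query_start, h.query_end, h.allele, h.percent_identity,
                      h.alignment_score, rank=i + 1)
            for i, h in enumerate(accepted)]


def number_domain(query_span: str, hit: DomainHit) -> NumberedDomain:
    """Transfer IMGT labels from the hit's reference onto the query span.

    The span is globally aligned to the allele's ungapped sequence.  A
    query residue matched to reference residue *r* receives the gapped
    alignment column of *r*; a query residue in an insertion column gets
    the preceding numeric label plus "a", "b", ...; unmatched reference
    columns are absent from the output.
    """
    if len(query_span) != hit.length:
        raise ArgumentError(
            f"query_span length {len(query_span)} does not match hit span "
            f"{hit.query_start}-{hit.query_end} (length {hit.length})")
    ali = align_pair(query_span, hit.allele.ungapped_seq, mode="global_query")
    colmap = gapped_position_map(hit.allele)
    residues: list[tuple[str, str]] = []
    last_numeric = 0
    insert_count = 0
    for q_idx, r_idx in ali.trace:
        if q_idx < 0:
            # deletion relative to the reference: hole in the numbering
            if r_idx >= 0:
                last_numeric = colmap[int(r_idx) + 1]
                insert_count = 0
            continue
        aa = query_span[int(q_idx)]
        if r_idx >= 0:
            last_numeric = colmap[int(r_idx) + 1]
            insert_count = 0
            label = str(last_numeric)
        else:
            insert_count += 1
            label = f"{last_numeric}{_insertion_suffix(insert_count)}"
        residues.append((label, aa))
    return NumberedDomain(domain_label=hit.domain_label, residues=tuple(residues))


def _insertion_suffix(n: int) -> str:
    """1 -> 'a', 2 -> 'b', ... 27 -> 'aa' (spreadsheet-style)."""
    out = ""
    while n > 0:
        n, rem = divmod(n - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def label_sort_key(label: str) -> tuple[int, str]:
    """Sort key placing '12' < '12a' < '12b' < '13'."""
    numeric = label.rstrip("abcdefghijklmnopqrstuvwxyz")
    return (int(numeric) if numeric else 0, label[len(numeric):])


def classify_chain(hits: list[DomainHit]) -> str:
    """Majority vote of chain class over hits, weighted by alignment score.

    Returns "H", "K", "L", or "ambiguous" when the top two classes tie.
    """
    if not hits:
        raise ArgumentError("classify_chain requires at least one domain hit")
    weights: dict[str, float] = {}
    for h in hits:
        weights[h.allele.chain_class] = weights.get(h.allele.chain_class, 0.0) + h.alignment_score
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "ambiguous"
    return ranked[0][0]
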