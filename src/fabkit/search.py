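"""Similarity search over an annotated antibody-structure collection.

Two search modes mirror the database front-end this package feeds: (i)
sequence similarity over the V region or the joint V+C region, for paired
or unpaired heavy/light queries, including batched repertoire inputs in
FASTA / AIRR TSV / CSV / 10x-contig-CSV dialects; and (ii) CH1-CL
interface similarity, comparing IMGT-label-indexed Calpha contact matrices
between entries (Jaccard index over the shared label support, with a
distance-correlation alternative).
"""

from __future__ import annotations

import csv as _csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArgumentError, BatchLimitError, ParseError
from .numbering import align_pair
from .structgeom import ContactMatrix

DEFAULT_MAX_BATCH = 200

#: AIRR-style column mapping; every entry can be overridden per call.
DEFAULT_AIRR_COLUMNS = {
    "sequence_id": "sequence_id",
    "cell_id": "cell_id",
    "locus": "locus",
    "sequence_aa": "sequence_aa",
}
DEFAULT_TENX_COLUMNS = {
    "sequence_id": "contig_id",
    "cell_id": "barcode",
    "locus": "chain",
    "sequence_aa": "sequence_aa",
}

HEAVY_LOCI = {"IGH"}
LIGHT_LOCI = {"IGK", "IGL"}


@dataclass(frozen=True)
class SearchQuery:
    query_id: str
    heavy_seq: str | None = None
    light_seq: str | None = None
    region: str = "V"  # "V" or "VC"

    def __post_init__(self) -> None:
        if not self.heavy_seq and not self.light_seq:
            raise ArgumentError(f"query {self.query_id!r}: neither heavy nor light "
                                "sequence present")


@dataclass(frozen=True)
class SearchHit:
    entry_id: str
    h_chain: str
    l_chain: str
    identity_h: float | None
    identity_l: float | None
    combined_identity: float
    rank: int


@dataclass
class SearchRecord:
    """Per-entry sequence views extracted from numbered domains."""

    entry_id: str
    h_chain_id: str = ""
    l_chain_id: str = ""
    h_v: str | None = None
    h_c: str | None = None
    l_v: str | None = None
    l_c: str | None = None
    ch1_cl: ContactMatrix | None = None

    def view(self, chain: str, region: str) -> str | None:
        v, c = (self.h_v, self.h_c) if chain == "H" else (self.l_v, self.l_c)
        if v is None:
            return None
        if region == "V":
            return v
        return v + c if c is not None else None  # VC view absent for V-only chains


@dataclass
class SearchIndex:
    entries: list[SearchRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def build_index(records: list[SearchRecord]) -> SearchIndex:
    """Index annotated entries for sequence and interface search.

    Records lacking any V-region numbering are skipped with a warning.
    """
    kept = []
    for rec in records:
        if rec.h_v is None and rec.l_v is None:
            warnings.warn(f"entry {rec.entry_id}: no numbered V domain; skipped "
                          "from the search index", stacklevel=2)
            continue
        kept.append(rec)
    return SearchIndex(entries=sorted(kept, key=lambda r: r.entry_id))


def seq_search(query: SearchQuery, db: SearchIndex, top_k: int = 10) -> list[SearchHit]:
    """Rank database entries by sequence identity to the query.

    Each present query chain is locally aligned against the matching
    region view of every entry; the combined identity is the unweighted
    mean over the query chains that found a view.  Ties break by entry_id.
    """
    if query.region not in ("V", "VC"):
        raise ArgumentError(f"unknown region {query.region!r}")
    scored: list[SearchHit] = []
    for rec in db.entries:
        identity_h = identity_l = None
        if query.heavy_seq:
            view = rec.view("H", query.region)
            if view:
                identity_h = align_pair(query.heavy_seq, view, mode="local").percent_identity
        if query.light_seq:
            view = rec.view("L", query.region)
            if view:
                identity_l = align_pair(query.light_seq, view, mode="local").percent_identity
        present = [x for x in (identity_h, identity_l) if x is not None]
        if not present:
            continue
        scored.append(SearchHit(rec.entry_id, rec.h_chain_id, rec.l_chain_id,
                                identity_h, identity_l,
                                combined_identity=float(np.mean(present)), rank=0))
    scored.sort(key=lambda h: (-h.combined_identity, h.entry_id))
    return [SearchHit(h.entry_id, h.h_chain, h.l_chain, h.identity_h, h.identity_l,
                      h.combined_identity, rank=i + 1)
            for i, h in enumerate(scored[:top_k])]


# ---------------------------------------------------------------------------
# repertoire parsing

def _parse_fasta_queries(path: Path) -> list[SearchQuery]:
    from Bio import SeqIO
    queries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        ident = rec.id
        low = ident.lower()
        # chain hint in the header; heavy by default
        if low.endswith(("_l", "|l")) or "light" in low:
            queries.append(SearchQuery(query_id=ident, light_seq=seq))
        else:
            queries.append(SearchQuery(query_id=ident, heavy_seq=seq))
    if not queries:
        raise ParseError(f"{path}: no FASTA records")
    return queries


def _parse_table_queries(path: Path, sep: str, columns: dict[str, str]) -> list[SearchQuery]:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse table: {exc}") from exc
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    col = columns
    queries: list[SearchQuery] = []
    for cell_id, group in df.groupby(col["cell_id"], sort=True, dropna=False):
        heavy = light = None
        extra: list[SearchQuery] = []
        for _, row in group.iterrows():
            locus = str(row[col["locus"]]).upper()
            seq = row[col["sequence_aa"]]
            if not isinstance(seq, str) or not seq:
                raise ParseError(
                    f"{path}: row {row[col['sequence_id']]!r} lacks an amino-acid "
                    "sequence (nucleotide-only repertoires are not translated)")
            seq = seq.upper()
            if locus in HEAVY_LOCI:
                if heavy is None:
                    heavy = seq
                else:
                    extra.append(SearchQuery(query_id=str(row[col["sequence_id"]]),
                                             heavy_seq=seq))
            elif locus in LIGHT_LOCI:
                if light is None:
                    light = seq
                else:
                    extra.append(SearchQuery(query_id=str(row[col["sequence_id"]]),
                                             light_seq=seq))
            else:
                raise ParseError(f"{path}: unknown locus {locus!r} for "
                                 f"{row[col['sequence_id']]!r}")
        if heavy is None and light is None:
            continue
        queries.append(SearchQuery(query_id=str(cell_id), heavy_seq=heavy,
                                   light_seq=light))
        if extra:
            warnings.warn(f"cell {cell_id!r}: surplus chains emitted as unpaired "
                          "queries", stacklevel=3)
            queries.extend(extra)
    return queries


def parse_repertoire(path: str | Path, dialect: str,
                     max_batch: int = DEFAULT_MAX_BATCH,
                     no_limit: bool = False,
                     column_map: dict[str, str] | None = None) -> list[SearchQuery]:
    """Read repertoire queries from one of the supported dialects.

    Dialects: ``fasta`` (unpaired records), ``airr_tsv``, ``csv`` (AIRR
    columns, comma-separated), ``tenx_contig_csv`` (rows paired by barcode,
    chain values IGH/IGK/IGL).  More than ``max_batch`` input records raise
    :class:`BatchLimitError` unless ``no_limit``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"repertoire file not found: {path}")
    if dialect == "fasta":
        queries = _parse_fasta_queries(path)
        n_records = len(queries)
    elif dialect in ("airr_tsv", "csv"):
        columns = {**DEFAULT_AIRR_COLUMNS, **(column_map or {})}
        sep = "\t" if dialect == "airr_tsv" else ","
        queries = _parse_table_queries(path, sep, columns)
        n_records = _count_table_rows(path, sep)
    elif dialect == "tenx_contig_csv":
        columns = {**DEFAULT_TENX_COLUMNS, **(column_map or {})}
        queries = _parse_table_queries(path, ",", columns)
        n_records = _count_table_rows(path, ",")
    else:
        raise ValueError(f"unknown repertoire dialect {dialect!r}")
    if not no_limit and n_records > max_batch:
        raise BatchLimitError(
            f"{n_records} records exceed the batch maximum of {max_batch}; "
            "pass no_limit to override")
    return queries


def _count_table_rows(path: Path, sep: str) -> int:
    with open(path) as fh:
        reader = _csv.reader(fh, delimiter=sep)
        return max(sum(1 for _ in reader) - 1, 0)


# ---------------------------------------------------------------------------
# interface similarity

def interface_similarity(a: ContactMatrix, b: ContactMatrix,
                         method: str = "jaccard") -> float:
    """Similarity in [0, 1] between two IMGT-indexed contact matrices.

    Both matrices are restricted to their shared (row, col) label support.
    ``jaccard``: Jaccard index of the two contact sets (empty union counts
    as identical).  ``distance``: Pearson correlation of the distances on
    the shared support, clipped to [0, 1].  No shared labels -> 0.0 with a
    warning.
    """
    if a.distances.size == 0 or b.distances.size == 0:
        raise ArgumentError("interface_similarity requires non-empty matrices")
    rows = [r for r in a.row_labels if r in set(b.row_labels)]
    cols = [c for c in a.col_labels if c in set(b.col_labels)]
    if not rows or not cols:
        warnings.warn("contact matrices share no labels; similarity 0", stacklevel=2)
        return 0.0
    ai = [a.row_labels.index(r) for r in rows]
    aj = [a.col_labels.index(c) for c in cols]
    bi = [b.row_labels.index(r) for r in rows]
    bj = [b.col_labels.index(c) for c in cols]
    da = a.distances[np.ix_(ai, aj)]
    db = b.distances[np.ix_(bi, bj)]
    valid = np.isfinite(da) & np.isfinite(db)
    if not valid.any():
        warnings.warn("no resolved positions on the shared support; similarity 0",
                      stacklevel=2)
        return 0.0
    if method == "jaccard":
        ca = (da <= a.cutoff) & valid
        cb = (db <= b.cutoff) & valid
        union = int(np.sum(ca | cb))
        if union == 0:
            return 1.0  # both contact sets empty on the shared support
        return float(np.sum(ca & cb) / union)
    if method == "distance":
        x, y = da[valid], db[valid]
        if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
            return 1.0 if np.allclose(x, y) else 0.0
        r = float(np.corrcoef(x, y)[0, 1])
        return float(np.clip(r, 0.0, 1.0))
    raise ValueError(f"unknown interface similarity method {method!r}")


@dataclass(frozen=True)
class InterfaceHit:
    entry_id: str
    similarity: float
    rank: int


def interface_search(query_matrix: ContactMatrix, db: SearchIndex,
                     top_k: int = 10, method: str = "jaccard") -> list[InterfaceHit]:
    """Rank entries by CH1-CL interface similarity to the query matrix."""
    scored = []
    for rec in db.entries:
        if rec.ch1_cl is None:
            continue
        sim = interface_similarity(query_matrix, rec.ch1_cl, method=method)
        scored.append((rec.entry_id, sim))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [InterfaceHit(entry_id=e, similarity=s, rank=i + 1)
            for i, (e, s) in enumerate(scored[:top_k])]
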