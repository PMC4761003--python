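"""k-mismatch search of siRNA passenger strands against a transcript database.

The database is curated mRNA FASTA (RefSeq-style: curated records carry an
``NM_`` accession prefix, predicted models ``XM_``); only curated records of
the configured organism are searched.  Queries are passenger-sense strands
and only transcript plus strands are scanned, because the passenger strand
is sequence-identical to the mRNA it silences.

Matching is Hamming-only (substitutions, no indels), with the allowed
distance escalated 0 → 1 → 2 → 3 until any hit is found.  The index uses the
pigeonhole principle: the query is split into k+1 disjoint seeds, so any
window within k mismatches must match at least one seed exactly; seed hits
are then verified by direct comparison.  A window containing N never matches
(each N position counts as a mismatch, even against another N).

``naive_hamming_scan`` is a deliberately independent reference: a vectorised
scan of every window of every record, used to cross-check the index in tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._seq import normalize, validate_iupac
from .align import Alignment, Scoring, window_alignment
from .errors import AmbiguousQueryError, DatabaseError, ParameterError
from .extraction import SirnaDuplex

__all__ = [
    "TranscriptRecord",
    "TranscriptIndex",
    "TargetHit",
    "QueryResult",
    "load_database",
    "parse_gene_symbol",
    "build_index",
    "search_at_most",
    "escalate_search",
    "count_by_distance",
    "resolve_query",
    "naive_hamming_scan",
]


@dataclass(frozen=True)
class TranscriptRecord:
    accession: str
    gene_symbol: str
    organism: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class TargetHit:
    """One matched window on a transcript plus strand."""

    accession: str
    gene_symbol: str
    position: int  # 0-based offset of the window on the transcript
    mismatches: int
    matched_window: str
    strand: str = "plus"
    alignment: Alignment | None = None

    def sort_key(self):
        return (self.mismatches, self.accession, self.position)


@dataclass
class TranscriptIndex:
    """Pigeonhole seed index over fixed-length windows of a transcript set.

    ``seed_slots`` holds ``(offset, length)`` pairs: max_mismatch+1 disjoint
    seeds tiling the query length (the trailing slots absorb the remainder).
    """

    records: list[TranscriptRecord]
    query_length: int
    max_mismatch: int
    seed_slots: list[tuple[int, int]]
    seed_table: dict[tuple[int, str], list[tuple[int, int]]]


# --------------------------------------------------------------------------
# database loading

_SYMBOL_RE = re.compile(r"\(([^()]+)\)")


def parse_gene_symbol(description: str) -> str | None:
    """Last parenthesized token before ", mRNA" in a RefSeq-style defline."""
    head = description.split(", mRNA")[0]
    symbols = _SYMBOL_RE.findall(head)
    if symbols and re.fullmatch(r"[A-Za-z0-9_.\-]+", symbols[-1]):
        return symbols[-1]
    return None


def load_database(
    fasta_path,
    accession_prefix: str = "NM_",
    organism: str | None = "Homo sapiens",
    symbol_table: dict[str, str] | None = None,
) -> list[TranscriptRecord]:
    """Load curated transcripts from FASTA, filtered by accession prefix and organism.

    Gene symbols are parsed from the definition line; an accession→symbol
    table (e.g. read from a two-column TSV) takes precedence, and records
    whose symbol cannot be parsed keep their accession as the symbol.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise DatabaseError(f"transcript database not found: {path}")
    records: list[TranscriptRecord] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        accession = rec.id
        if accession_prefix and not accession.startswith(accession_prefix):
            continue
        desc = rec.description
        if organism and organism not in desc:
            continue
        symbol = None
        if symbol_table:
            symbol = symbol_table.get(accession) or symbol_table.get(accession.split(".")[0])
        if symbol is None:
            symbol = parse_gene_symbol(desc)
        if symbol is None:
            symbol = accession
        records.append(
            TranscriptRecord(
                accession=accession,
                gene_symbol=symbol,
                organism=organism or "",
                sequence=normalize(str(rec.seq)),
                description=desc,
            )
        )
    if n_seen == 0:
        raise DatabaseError(f"no FASTA records in {path}")
    if not records:
        raise DatabaseError(
            f"no records left after filtering {path} "
            f"(accession_prefix={accession_prefix!r}, organism={organism!r})"
        )
    return records


def load_symbol_table(tsv_path) -> dict[str, str]:
    """Two-column accession<TAB>symbol file, no header."""
    table = {}
    for line in Path(tsv_path).read_text().splitlines():
        if not line.strip():
            continue
        acc, _, sym = line.partition("\t")
        table[acc.strip()] = sym.strip()
    return table


# --------------------------------------------------------------------------
# index construction and search

def _seed_slots(query_length: int, max_mismatch: int) -> list[tuple[int, int]]:
    k = max_mismatch + 1
    base, rem = divmod(query_length, k)
    lengths = [base + (1 if i >= k - rem else 0) for i in range(k)]
    slots, off = [], 0
    for ln in lengths:
        slots.append((off, ln))
        off += ln
    return slots


def build_index(
    records: list[TranscriptRecord], query_length: int, max_mismatch: int = 3
) -> TranscriptIndex:
    """Build the pigeonhole seed index for fixed-length queries."""
    if not 0 <= max_mismatch <= 3:
        raise ParameterError(f"max_mismatch must be in [0, 3], got {max_mismatch}")
    if query_length < max_mismatch + 1:
        raise ParameterError(
            f"query_length {query_length} shorter than the {max_mismatch + 1} required seeds"
        )
    slots = _seed_slots(query_length, max_mismatch)
    table: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for ri, rec in enumerate(records):
        seq = rec.sequence
        for w in range(len(seq) - query_length + 1):
            for si, (off, ln) in enumerate(slots):
                key = (si, seq[w + off : w + off + ln])
                table.setdefault(key, []).append((ri, w))
    return TranscriptIndex(
        records=list(records),
        query_length=query_length,
        max_mismatch=max_mismatch,
        seed_slots=slots,
        seed_table=table,
    )


def _hamming_n(a: str, b: str, limit: int) -> int:
    """Hamming distance where any N mismatches everything (including N)."""
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            d += 1
            if d > limit:
                return d
    return d


def _check_query(passenger: str, index: TranscriptIndex, k: int) -> str:
    if not 0 <= k <= index.max_mismatch:
        raise ParameterError(
            f"k={k} outside the index's guaranteed range [0, {index.max_mismatch}]"
        )
    p = normalize(passenger)
    if len(p) != index.query_length:
        raise ParameterError(
            f"query length {len(p)} does not match index query_length {index.query_length}"
        )
    return p


def search_at_most(passenger: str, index: TranscriptIndex, k: int) -> list[TargetHit]:
    """All plus-strand windows within Hamming distance k, sorted by
    (mismatches, accession, position); one hit per (accession, position)."""
    p = _check_query(passenger, index, k)
    q = index.query_length
    seen: set[tuple[int, int]] = set()
    hits: list[TargetHit] = []
    for si, (off, ln) in enumerate(index.seed_slots):
        for ri, w in index.seed_table.get((si, p[off : off + ln]), ()):
            if (ri, w) in seen:
                continue
            seen.add((ri, w))
            rec = index.records[ri]
            window = rec.sequence[w : w + q]
            d = _hamming_n(p, window, k)
            if d <= k:
                hits.append(
                    TargetHit(
                        accession=rec.accession,
                        gene_symbol=rec.gene_symbol,
                        position=w,
                        mismatches=d,
                        matched_window=window,
                    )
                )
    hits.sort(key=TargetHit.sort_key)
    return hits


def escalate_search(
    passenger: str, index: TranscriptIndex, k_min: int = 0, k_max: int = 3
) -> tuple[int | None, list[TargetHit]]:
    """Search in ascending mismatch order until hitting an alignment.

    Returns the smallest k in [k_min, k_max] with a non-empty exact-distance
    hit set and all hits at exactly that distance; (None, []) if nothing lies
    within k_max.
    """
    if k_min > k_max:
        raise ParameterError(f"k_min {k_min} > k_max {k_max}")
    all_hits = search_at_most(passenger, index, min(k_max, index.max_mismatch))
    for k in range(k_min, k_max + 1):
        level = [h for h in all_hits if h.mismatches == k]
        if level:
            return k, level
    return None, []


def count_by_distance(passenger: str, index: TranscriptIndex) -> tuple[int, int, int, int]:
    """Distinct target genes at exact distances 0..3 (a gene counts at every
    distance where it has at least one hit)."""
    hits = search_at_most(passenger, index, index.max_mismatch)
    genes: list[set[str]] = [set(), set(), set(), set()]
    for h in hits:
        genes[h.mismatches].add(h.gene_symbol)
    return tuple(len(g) for g in genes)  # type: ignore[return-value]


@dataclass
class QueryResult:
    """Outcome of the full search for one extracted duplex."""

    query_name: str
    duplex: SirnaDuplex
    k_used: int | None
    hits: list[TargetHit]
    n_target_genes: int
    read_sequence: str | None = None
    error: str | None = None

    @property
    def target_genes(self) -> list[str]:
        seen, out = set(), []
        for h in self.hits:
            if h.gene_symbol not in seen:
                seen.add(h.gene_symbol)
                out.append(h.gene_symbol)
        return out


def resolve_query(
    duplex: SirnaDuplex,
    index: TranscriptIndex,
    k_min: int = 0,
    k_max: int = 3,
    scoring: Scoring | None = None,
    allow_ambiguous: bool = False,
    read_sequence: str | None = None,
) -> QueryResult:
    """Run the escalating search for a duplex and attach display alignments.

    The passenger strand is always the search input (when extraction was run
    in guide mode the passenger was already reconstructed as the guide's
    reverse complement), so hits are passenger-vs-plus-strand by construction.
    """
    if duplex.has_ambiguous and not allow_ambiguous:
        raise AmbiguousQueryError(
            f"duplex from {duplex.source_name!r} contains ambiguous bases; "
            "pass allow_ambiguous=True to search anyway"
        )
    k_used, hits = escalate_search(duplex.passenger, index, k_min, k_max)
    # Full-window gapless display alignment: a strictly local alignment could
    # trim terminal mismatches and misstate the hit's mismatch level.
    aligned = [
        replace(h, alignment=window_alignment(duplex.passenger, h.matched_window, scoring))
        for h in hits
    ]
    genes = {h.gene_symbol for h in aligned}
    return QueryResult(
        query_name=duplex.source_name,
        duplex=duplex,
        k_used=k_used,
        hits=aligned,
        n_target_genes=len(genes),
        read_sequence=read_sequence,
    )


# --------------------------------------------------------------------------
# independent reference scan

def naive_hamming_scan(
    passenger: str, records: list[TranscriptRecord], k: int
) -> list[TargetHit]:
    """Brute-force reference: score every window of every record.

    Vectorised but structurally independent of the seed index; used as the
    oracle in equivalence tests and useful on its own for tiny databases.
    """
    p = validate_iupac(passenger, "query")
    q = np.frombuffer(p.encode(), dtype=np.uint8)
    n_code = ord("N")
    hits: list[TargetHit] = []
    for rec in records:
        s = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        if len(s) < len(q):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(s, len(q))
        mism = (windows != q).sum(axis=1)
        # N always mismatches: add back positions that compared equal as N-N,
        # and count query-N positions that happened to match.
        n_pos = (windows == n_code) | (q == n_code)
        mism = mism + ((windows == q) & n_pos).sum(axis=1)
        for w in np.nonzero(mism <= k)[0]:
            w = int(w)
            hits.append(
                TargetHit(
                    accession=rec.accession,
                    gene_symbol=rec.gene_symbol,
                    position=w,
                    mismatches=int(mism[w]),
                    matched_window=rec.sequence[w : w + len(p)],
                )
            )
    hits.sort(key=TargetHit.sort_key)
    return hits
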