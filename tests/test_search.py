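"""Database loading, pigeonhole index, and k-mismatch search semantics."""

import random

import pytest

from shrnascan.errors import AmbiguousQueryError, DatabaseError, ParameterError
from shrnascan.extraction import SirnaDuplex, extract_sirna, parse_pattern
from shrnascan.search import (
    _seed_slots,
    build_index,
    count_by_distance,
    escalate_search,
    load_database,
    naive_hamming_scan,
    parse_gene_symbol,
    resolve_query,
    search_at_most,
)
from shrnascan._seq import reverse_complement

from conftest import make_records


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestLoadDatabase:
    def test_filters_and_symbol_parsing(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(
            ">NM_000001.1 Homo sapiens widget kinase (WGT1), mRNA\nACGTACGTACGT\n"
            ">XM_000002.1 Homo sapiens predicted gene (PRD2), mRNA\nACGTACGTACGT\n"
            ">NM_000003.1 Mus musculus other kinase (OTK1), mRNA\nACGTACGTACGT\n"
            ">NM_000004.1 Homo sapiens unparsable defline\nACGTACGTACGT\n"
            ">NM_000005.1 Homo sapiens thing (alias A) protein (THG5), mRNA\nACGT\n"
        )
        records = load_database(fasta)
        assert [r.accession for r in records] == ["NM_000001.1", "NM_000004.1", "NM_000005.1"]
        by_acc = {r.accession: r.gene_symbol for r in records}
        assert by_acc["NM_000001.1"] == "WGT1"
        assert by_acc["NM_000004.1"] == "NM_000004.1"  # fallback to accession
        assert by_acc["NM_000005.1"] == "THG5"  # last parenthesized token wins

    def test_symbol_table_takes_precedence(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(">NM_000001.1 Homo sapiens old name (HTATIP), mRNA\nACGTACGT\n")
        (rec,) = load_database(fasta, symbol_table={"NM_000001.1": "KAT5"})
        assert rec.gene_symbol == "KAT5"

    def test_empty_after_filter_raises(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(">XM_1.1 Homo sapiens x (X1), mRNA\nACGT\n")
        with pytest.raises(DatabaseError, match="NM_"):
            load_database(fasta)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(DatabaseError):
            load_database(tmp_path / "absent.fasta")


def test_gene_symbol_parsing_convention():
    assert parse_gene_symbol("NM_1.1 Homo sapiens widget kinase (WGT1), mRNA") == "WGT1"
    assert parse_gene_symbol("NM_1.1 Homo sapiens nothing here, mRNA") is None


class TestIndexStructure:
    def test_19mer_three_mismatch_partition(self):
        assert _seed_slots(19, 3) == [(0, 4), (4, 5), (9, 5), (14, 5)]

    def test_exact_match_degenerate_partition(self):
        assert _seed_slots(19, 0) == [(0, 19)]

    def test_empty_record_list_searches_empty(self):
        index = build_index([], query_length=19, max_mismatch=3)
        assert search_at_most("A" * 19, index, 3) == []

    def test_too_short_query_rejected(self):
        with pytest.raises(ParameterError):
            build_index([], query_length=3, max_mismatch=3)

    def test_k_out_of_range_rejected(self):
        index = build_index(make_records(["A" * 40]), 19, max_mismatch=2)
        with pytest.raises(ParameterError):
            search_at_most("A" * 19, index, 3)


class TestSearchSemantics:
    def test_exact_self_match(self, rng):
        query = _random_seq(rng, 19)
        seq = _random_seq(rng, 60) + query + _random_seq(rng, 60)
        index = build_index(make_records([seq]), 19, 3)
        hits = search_at_most(query, index, 0)
        assert [(h.position, h.mismatches) for h in hits] == [(60, 0)]

    def test_distance_filtering(self, rng):
        query = _random_seq(rng, 19)
        d1 = _mutate(query, [3], rng)
        d3 = _mutate(query, [0, 9, 18], rng)
        records = make_records(["T" * 30 + d1 + "T" * 30, "T" * 30 + d3 + "T" * 30])
        index = build_index(records, 19, 3)
        hits = search_at_most(query, index, 2)
        assert [(h.accession, h.mismatches) for h in hits] == [("NM_900001.1", 1)]

    def test_escalation_stops_at_minimal_level(self, rng):
        query = _random_seq(rng, 19)
        d2 = _mutate(query, [2, 11], rng)
        d3 = _mutate(query, [1, 7, 15], rng)
        index = build_index(
            make_records(["A" * 25 + d2 + "A" * 25, "A" * 25 + d3 + "A" * 25]), 19, 3
        )
        k_used, hits = escalate_search(query, index)
        assert k_used == 2
        assert all(h.mismatches == 2 for h in hits)

    def test_escalation_none_when_nothing_within_three(self):
        # mirrors a library clone with no RefSeq neighbour at any level
        query = "GCGTAATCGGGCGAATAAC"
        index = build_index(make_records(["A" * 100]), 19, 3)
        assert escalate_search(query, index) == (None, [])
        assert count_by_distance(query, index) == (0, 0, 0, 0)

    def test_gene_level_collapse_of_isoforms(self, rng):
        query = _random_seq(rng, 19)
        d1a, d1b = _mutate(query, [4], rng), _mutate(query, [12], rng)
        records = make_records(
            ["C" * 20 + d1a + "C" * 20, "C" * 20 + d1b + "C" * 20],
            gene_symbols=["SAME", "SAME"],
        )
        index = build_index(records, 19, 3)
        assert count_by_distance(query, index) == (0, 1, 0, 0)
        k_used, hits = escalate_search(query, index)
        assert k_used == 1 and len(hits) == 2  # two transcripts, one gene

    def test_n_window_never_matches(self):
        query = "A" * 19
        index = build_index(make_records(["A" * 9 + "N" + "A" * 9]), 19, 3)
        hits = search_at_most(query, index, 3)
        assert [(h.position, h.mismatches) for h in hits] == [(0, 1)]
        index0 = build_index(make_records(["A" * 9 + "N" + "A" * 9]), 19, 0)
        assert search_at_most(query, index0, 0) == []

    def test_hits_nest_and_partition(self, small_index, small_transcriptome):
        _, _, queries = small_transcriptome
        for q in queries:
            by_k = [search_at_most(q, small_index, k) for k in range(4)]
            keyed = [{(h.accession, h.position) for h in hits} for hits in by_k]
            for k in range(3):
                assert keyed[k] <= keyed[k + 1]
            levels = [
                {(h.accession, h.position) for h in by_k[3] if h.mismatches == d}
                for d in range(4)
            ]
            assert set.union(*levels) == keyed[3]
            assert sum(len(lv) for lv in levels) == len(keyed[3])

    def test_index_matches_naive_oracle_on_random_fixture(self):
        rng = random.Random(77)
        records = make_records([_random_seq(rng, rng.randint(150, 250)) for _ in range(40)])
        index = build_index(records, 19, 3)
        for _ in range(25):
            if rng.random() < 0.5:
                query = _random_seq(rng, 19)
            else:  # near-copy of a real window, to exercise non-empty hit sets
                rec = rng.choice(records)
                w = rng.randrange(len(rec.sequence) - 19)
                query = _mutate(rec.sequence[w : w + 19], rng.sample(range(19), rng.randint(0, 3)), rng)
            for k in range(4):
                got = [(h.accession, h.position, h.mismatches) for h in search_at_most(query, index, k)]
                want = [(h.accession, h.position, h.mismatches) for h in naive_hamming_scan(query, records, k)]
                assert got == want


class TestResolveQuery:
    def test_single_transcript_reports_one_gene_zero_mismatches(self):
        # report shape (1 gene, 0 mismatches) for a validated passenger
        passenger = "GATTATCCAAAGAGGTTCT"
        records = make_records(["G" * 33 + passenger + "G" * 33], gene_symbols=["RPS6KA6"])
        index = build_index(records, 19, 3)
        read = ("clone1", "CC" + "TATAGAAAAAA" + passenger + "GG")
        (duplex,) = extract_sirna(read, parse_pattern("tatagaaaaaa(.{ 19 })"))
        result = resolve_query(duplex, index)
        assert (result.n_target_genes, result.k_used) == (1, 0)
        assert result.target_genes == ["RPS6KA6"]
        assert result.hits[0].alignment.n_gaps == 0

    def test_no_target_renders_empty(self, rng):
        duplex = _make_duplex(_random_seq(rng, 19))
        index = build_index(make_records(["T" * 80]), 19, 3)
        result = resolve_query(duplex, index)
        assert (result.k_used, result.hits, result.n_target_genes) == (None, [], 0)

    def test_two_genes_at_distance_one(self, rng):
        query = _random_seq(rng, 19)
        a, b = _mutate(query, [5], rng), _mutate(query, [9], rng)
        records = make_records(["G" * 22 + a + "G" * 22, "G" * 22 + b + "G" * 22])
        index = build_index(records, 19, 3)
        result = resolve_query(_make_duplex(query), index)
        assert (result.n_target_genes, result.k_used) == (2, 1)

    def test_ambiguous_duplex_rejected_by_default(self):
        duplex = _make_duplex("GATTATCCANAGAGGTTCT")
        index = build_index(make_records(["A" * 50]), 19, 3)
        with pytest.raises(AmbiguousQueryError):
            resolve_query(duplex, index)
        assert resolve_query(duplex, index, allow_ambiguous=True).k_used is None


def _make_duplex(passenger):
    return SirnaDuplex(
        passenger=passenger,
        guide=reverse_complement(passenger),
        source_name="q",
        source_start=0,
        source_end=len(passenger),
        source_orientation="forward",
        gc_percent=50.0,
        has_ambiguous="N" in passenger,
    )
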