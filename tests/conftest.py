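import random

import pytest

from shrnascan.search import TranscriptRecord, build_index
from shrnascan.simulate import FixtureSpec, Planting, generate_transcriptome, random_passengers


@pytest.fixture(scope="session")
def small_transcriptome():
    """50 transcripts with 8 planted queries, one per distance 0-3 (twice)."""
    queries = random_passengers(8, seed=11)
    spec = FixtureSpec(
        n_transcripts=50,
        length_range=(500, 800),
        plantings=[Planting(q, i % 4) for i, q in enumerate(queries)],
        seed=11,
    )
    records, truth = generate_transcriptome(spec)
    return records, truth, queries


@pytest.fixture(scope="session")
def small_index(small_transcriptome):
    records, truth, queries = small_transcriptome
    nm = [r for r in records if r.accession.startswith("NM_")]
    return build_index(nm, query_length=19, max_mismatch=3)


def make_records(seqs, gene_symbols=None):
    """Tiny hand-built transcript sets for targeted tests."""
    out = []
    for i, seq in enumerate(seqs):
        sym = gene_symbols[i] if gene_symbols else f"G{i + 1}"
        out.append(
            TranscriptRecord(
                accession=f"NM_{900001 + i}.1",
                gene_symbol=sym,
                organism="Homo sapiens",
                sequence=seq,
                description=f"NM_{900001 + i}.1 Homo sapiens test gene ({sym}), mRNA",
            )
        )
    return out


@pytest.fixture()
def rng():
    return random.Random(1234)
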