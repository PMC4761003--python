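"""Synthetic fixtures: transcriptomes with planted targets, shRNA clone
reads, and two-condition expression DataSets.

Every generator is fully determined by its seed and emits a truth table, so
each pipeline stage can be scored exactly without re-deriving anything:

* ``generate_transcriptome`` plants query windows at known Hamming distances
  into random RefSeq-style transcripts (an NM_/XM_ mix) and then scrubs the
  background, re-randomising any accidental window within distance 3 of a
  planted query so the truth table is exhaustive.  The scrub is a fixture
  property (it makes recovery tests exact), not a biological claim.
* ``generate_clone_reads`` assembles hairpin-coding reads as
  pad + vector flank + passenger + loop + reverse-complement(passenger) + pad,
  emitting half of them reverse-complemented to exercise orientation
  invariance.  The default loop TTCAAGAGA is a common shRNA loop used purely
  as a fixture constant.
* ``generate_datasets`` draws gaussian within-group values, shifts planted
  genes by ``effect_size`` standard deviations in one condition, and adds
  deliberate violators of each dataset-selection rule.

Defaults describe the study conditions the test-bed assumes throughout:
200 transcripts of 1–2 kb at GC 0.5, 19-nt siRNAs, 20 DataSets of 2 × 5
samples, a 3-SD planted effect.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import reverse_complement
from .errors import ParameterError
from .expression import ExpressionDataSet, write_dataset
from .search import TranscriptRecord, naive_hamming_scan

__all__ = [
    "Planting",
    "FixtureSpec",
    "generate_transcriptome",
    "generate_clone_reads",
    "generate_datasets",
    "random_passengers",
    "write_fasta",
    "DEFAULT_FLANK",
    "DEFAULT_LOOP",
]

DEFAULT_FLANK = "TATAGAAAAAA"  # vector sequence preceding the sense strand
DEFAULT_LOOP = "TTCAAGAGA"  # common shRNA stem loop; fixture constant only

_BASES = "ACGT"


@dataclass(frozen=True)
class Planting:
    """One target site to embed: ``query`` at ``distance`` substitutions."""

    query: str
    distance: int
    transcript_index: int | None = None  # None: choose at random (NM_ records)
    position: int | None = None

    def __post_init__(self):
        if not 0 <= self.distance <= 3:
            raise ParameterError(f"planting distance must be in [0, 3], got {self.distance}")


@dataclass
class FixtureSpec:
    n_transcripts: int = 200
    length_range: tuple[int, int] = (1000, 2000)
    gc_bias: float = 0.5
    plantings: list[Planting] = field(default_factory=list)
    xm_fraction: float = 0.1  # predicted-model decoys, excluded by the NM_ filter
    n_datasets: int = 20
    groups_per_dataset: int = 2
    samples_per_group: int = 5
    effect_size: float = 3.0  # planted shift, in within-group SD units
    n_background_genes: int = 30
    seed: int = 0


def _random_base(rng: random.Random, gc_bias: float) -> str:
    if rng.random() < gc_bias:
        return "G" if rng.random() < 0.5 else "C"
    return "A" if rng.random() < 0.5 else "T"


def _random_seq(rng: random.Random, length: int, gc_bias: float) -> list[str]:
    return [_random_base(rng, gc_bias) for _ in range(length)]


def _mutate(query: str, distance: int, rng: random.Random) -> str:
    """A copy of ``query`` with exactly ``distance`` substitutions."""
    out = list(query)
    for pos in rng.sample(range(len(query)), distance):
        out[pos] = rng.choice([b for b in _BASES if b != out[pos]])
    return "".join(out)


def random_passengers(
    n: int, length: int = 19, seed: int = 0, first_base: str | None = "G"
) -> list[str]:
    """Random siRNA passenger strands (default: G-initiated 19-mers, the
    shape of a pol III random-oligonucleotide library insert)."""
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        seq = [rng.choice(_BASES) for _ in range(length)]
        if first_base:
            seq[0] = first_base
        out.append("".join(seq))
    return out


def _overlaps(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def generate_transcriptome(
    spec: FixtureSpec,
    out_fasta=None,
    out_truth=None,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Random transcripts with planted target sites and an exhaustive truth table.

    Returns all records (curated NM_ plus XM_ decoys) and a truth DataFrame
    with columns query, accession, gene_symbol, position, distance covering
    every window of any NM_ record within Hamming distance 3 of any planted
    query.  Optionally writes FASTA and truth TSV.
    """
    rng = random.Random(spec.seed)
    lo, hi = spec.length_range
    n_xm = int(round(spec.n_transcripts * spec.xm_fraction))
    n_nm = spec.n_transcripts - n_xm
    if spec.plantings and n_nm == 0:
        raise ParameterError("cannot plant into a transcriptome with no NM_ records")

    nm_seqs = [_random_seq(rng, rng.randint(lo, hi), spec.gc_bias) for _ in range(n_nm)]
    planted_intervals: list[list[tuple[int, int]]] = [[] for _ in range(n_nm)]
    truth_rows = []

    for planting in spec.plantings:
        q = planting.query.upper().replace("U", "T")
        ri = (
            planting.transcript_index
            if planting.transcript_index is not None
            else rng.randrange(n_nm)
        )
        seq = nm_seqs[ri]
        if len(seq) < len(q):
            raise ParameterError(
                f"transcript {ri} (len {len(seq)}) too short for a {len(q)}-nt planting"
            )
        if planting.position is not None:
            pos = planting.position
            if pos + len(q) > len(seq) or _overlaps(planted_intervals[ri], pos, pos + len(q)):
                raise ParameterError(f"infeasible planting at transcript {ri} position {pos}")
        else:
            for _ in range(200):
                pos = rng.randrange(len(seq) - len(q) + 1)
                if not _overlaps(planted_intervals[ri], pos, pos + len(q)):
                    break
            else:
                raise ParameterError(f"could not place planting on transcript {ri}")
        window = _mutate(q, planting.distance, rng)
        seq[pos : pos + len(q)] = list(window)
        planted_intervals[ri].append((pos, pos + len(q)))
        truth_rows.append((q, ri, pos, planting.distance))

    # Scrub accidental near-matches so the truth table is exhaustive.
    queries = sorted({row[0] for row in truth_rows})
    truth_sites = {(q, ri, pos) for q, ri, pos, _ in truth_rows}
    if queries:
        for _pass in range(50):
            tmp_records = [
                TranscriptRecord(f"tmp_{i}", f"tmp_{i}", "", "".join(s)) for i, s in enumerate(nm_seqs)
            ]
            offenders = []
            for q in queries:
                for hit in naive_hamming_scan(q, tmp_records, 3):
                    ri = int(hit.accession.split("_")[1])
                    if (q, ri, hit.position) not in truth_sites:
                        offenders.append((q, ri, hit.position))
            if not offenders:
                break
            for q, ri, pos in offenders:
                free = [
                    j
                    for j in range(pos, pos + len(q))
                    if not _overlaps(planted_intervals[ri], j, j + 1)
                ]
                if not free:
                    raise ParameterError(
                        "scrub failed: accidental match fully inside a planted window "
                        "(queries too similar)"
                    )
                j = rng.choice(free)
                nm_seqs[ri][j] = rng.choice([b for b in _BASES if b != nm_seqs[ri][j]])
        else:
            raise ParameterError("background scrub did not converge in 50 passes")

    records: list[TranscriptRecord] = []
    for i, seq in enumerate(nm_seqs):
        acc, sym = f"NM_{100001 + i}.1", f"GENE{i + 1}"
        records.append(
            TranscriptRecord(
                accession=acc,
                gene_symbol=sym,
                organism="Homo sapiens",
                sequence="".join(seq),
                description=f"{acc} Homo sapiens synthetic transcript {i + 1} ({sym}), mRNA",
            )
        )
    for j in range(n_xm):
        acc, sym = f"XM_{200001 + j}.1", f"PRD{j + 1}"
        records.append(
            TranscriptRecord(
                accession=acc,
                gene_symbol=sym,
                organism="Homo sapiens",
                sequence="".join(_random_seq(rng, rng.randint(lo, hi), spec.gc_bias)),
                description=f"{acc} PREDICTED: Homo sapiens synthetic model {j + 1} ({sym}), mRNA",
            )
        )

    truth = pd.DataFrame(
        [
            (q, records[ri].accession, records[ri].gene_symbol, pos, dist)
            for q, ri, pos, dist in truth_rows
        ],
        columns=["query", "accession", "gene_symbol", "position", "distance"],
    )
    if out_fasta is not None:
        write_fasta([(f"{r.accession} {r.description.split(' ', 1)[1]}" if r.description else r.accession, r.sequence) for r in records], out_fasta)
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return records, truth


def write_fasta(named_seqs: list[tuple[str, str]], path, width: int = 70) -> None:
    """Plain FASTA writer (header may include a description after the id)."""
    with open(path, "w") as fh:
        for header, seq in named_seqs:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_clone_reads(
    passengers: list[str] | list[tuple[str, str]],
    flank: str = DEFAULT_FLANK,
    loop: str = DEFAULT_LOOP,
    seed: int = 0,
    pad_range: tuple[int, int] = (5, 30),
    out_fasta=None,
) -> list[tuple[str, str]]:
    """shRNA-coding clone reads: pad + flank + passenger + loop + antisense + pad.

    Every odd-indexed read is emitted reverse-complemented, modelling the
    fact that sequencing direction is arbitrary for an inverted repeat.
    """
    if not flank:
        raise ParameterError("flank must be non-empty")
    if len(loop) < 3:
        raise ParameterError("loop must be at least 3 nt")
    rng = random.Random(seed)
    reads: list[tuple[str, str]] = []
    for i, item in enumerate(passengers):
        name, passenger = item if isinstance(item, tuple) else (f"clone_{i + 1:03d}", item)
        passenger = passenger.upper().replace("U", "T")
        pad5 = "".join(rng.choice(_BASES) for _ in range(rng.randint(*pad_range)))
        pad3 = "".join(rng.choice(_BASES) for _ in range(rng.randint(*pad_range)))
        read = pad5 + flank.upper() + passenger + loop.upper() + reverse_complement(passenger) + pad3
        if i % 2 == 1:
            read = reverse_complement(read)
        reads.append((name, read))
    if out_fasta is not None:
        write_fasta(reads, out_fasta)
    return reads


def generate_datasets(
    spec: FixtureSpec,
    planted_genes: list[str],
    out_dir=None,
) -> tuple[list[ExpressionDataSet], pd.DataFrame]:
    """Expression DataSets with known filter status and planted shifts.

    ``spec.n_datasets`` well-formed human two-condition datasets are
    generated (planted genes shifted by ``effect_size`` SD in the second
    condition of every one), followed by three deliberate violators: wrong
    organism, three subsets, and a subset with only two samples.  The truth
    table lists each dataset's pass/fail status and the rule it breaks.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(dict.fromkeys(planted_genes)) + [
        f"BG{i + 1}" for i in range(spec.n_background_genes)
    ]
    datasets: list[ExpressionDataSet] = []
    truth_rows = []

    def matrix(samples: list[str], shifted: set[str], shift_samples: list[str]) -> pd.DataFrame:
        values = rng.normal(8.0, 1.0, size=(len(genes), len(samples)))
        df = pd.DataFrame(values, index=genes, columns=samples)
        for g in shifted:
            df.loc[g, shift_samples] += spec.effect_size
        return df

    n = spec.samples_per_group
    for i in range(spec.n_datasets):
        ds_id = f"GDS_S{i + 1:03d}"
        a = [f"{ds_id}_A{j + 1}" for j in range(n)]
        b = [f"{ds_id}_B{j + 1}" for j in range(n)]
        datasets.append(
            ExpressionDataSet(
                dataset_id=ds_id,
                organism="Homo sapiens",
                subset_type="agent",
                subsets=[("control", a), ("treated", b)],
                values=matrix(a + b, set(planted_genes), b),
                source_url=f"https://example.org/geo/{ds_id}",
            )
        )
        truth_rows.append((ds_id, True, ""))

    violators = [
        ("GDS_V_ORG", "Mus musculus", [("control", n), ("treated", n)], "organism"),
        ("GDS_V_3SUB", "Homo sapiens", [("low", n), ("mid", n), ("high", n)], "n_subsets"),
        ("GDS_V_N2", "Homo sapiens", [("control", 2), ("treated", max(n, 3))], "min_samples"),
    ]
    for ds_id, org, groups, rule in violators:
        subsets, samples = [], []
        for gi, (label, size) in enumerate(groups):
            ids = [f"{ds_id}_{label}{j + 1}" for j in range(size)]
            subsets.append((label, ids))
            samples.extend(ids)
        datasets.append(
            ExpressionDataSet(
                dataset_id=ds_id,
                organism=org,
                subset_type="agent",
                subsets=subsets,
                values=pd.DataFrame(
                    rng.normal(8.0, 1.0, size=(len(genes), len(samples))),
                    index=genes,
                    columns=samples,
                ),
                source_url=f"https://example.org/geo/{ds_id}",
            )
        )
        truth_rows.append((ds_id, False, rule))

    truth = pd.DataFrame(truth_rows, columns=["dataset_id", "passes", "failed_rule"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ds in datasets:
            write_dataset(ds, out / ds.dataset_id)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return datasets, truth
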