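# shrnascan

Offline target prediction for shRNA screening with random-oligonucleotide
RNAi libraries.

In such screens every recovered shRNA clone must be sequenced and its ~19-nt
siRNA mapped back to candidate target mRNAs — including near-matches, because
an siRNA can silence transcripts it matches with a few mismatches.
`shrnascan` automates that analysis end to end, entirely on local files:

1. **Extraction** — locate the siRNA inside an shRNA-coding clone read using
   a vector-flank pattern such as `tatagaaaaaa(.{ 19 })` (the literal vector
   sequence followed by a 19-base capture). Because the hairpin-coding DNA is
   an inverted repeat, both the read and its reverse complement are scanned,
   so sequencing direction never matters. The captured strand is the
   passenger (sense) strand by default, or the guide with `--guide`.
2. **Search** — find every plus-strand window of a curated mRNA database
   (RefSeq-style FASTA, `NM_`-prefixed records of the chosen organism)
   within Hamming distance *k* of the passenger, escalating
   *k* = 0 → 1 → 2 → 3 until any hit is found. The index is a pigeonhole
   seed table: a 19-mer query is split into *k*+1 disjoint seeds
   (4+5+5+5 for *k* = 3), so any window within *k* substitutions matches at
   least one seed exactly; seed hits are then verified directly. Hits are
   collapsed to distinct genes per mismatch level.
3. **Alignment** — each hit is displayed as a full-window base-by-base
   alignment; a general Smith–Waterman local aligner (match +2, mismatch −1,
   gap −2; configurable) is also provided.
4. **Expression** — genes are tested in two-condition expression DataSets
   (gene × sample matrices with subset metadata). A dataset is used when it
   compares exactly two conditions of one experimental variable with ≥ 3
   samples each; a gene is flagged when Welch's unequal-variance *t*-test
   gives two-sided *P* < 0.01. No multiple-testing correction is applied —
   the flag is a raw per-dataset threshold by design.
5. **Annotation & report** — gene symbols join a local annotation TSV
   (synonym-aware, e.g. a legacy alias resolves to the current symbol) with
   URL templates for HGNC, GO, OMIM, PubMed, miRTarBase, REACTOME and HPRD,
   and the run is written as a summary CSV, one self-contained HTML page per
   query, and a zip — HTML names are 20 random alphanumerics plus a
   `YYYYMMDDhhmmss` timestamp to prevent collisions.

A synthetic-fixture module generates all three input kinds (transcriptomes
with planted targets, hairpin clone reads, expression DataSets) together
with truth tables, so the whole pipeline is testable without any download.

## Worked example

Generate a synthetic test-bed (40 transcripts, 5 clone reads whose siRNAs
were planted at mismatch distances 0, 1, 2, 3, 0) and run the pipeline:

```bash
shrnascan simulate --out demo --seed 42 --n-transcripts 40 --n-queries 5 --n-datasets 6
shrnascan run --queries demo/clone_reads.fasta --db demo/transcripts.fasta \
              --datasets demo/datasets --out demo/out --seed 42 --frozen-clock
cat demo/out/shrnascan_run.csv
```

```
query_name,passenger,guide,gc_percent,k_used,n_target_genes,html_file_name
clone_001,GAGCCCAATAAACCACTCT,AGAGTGGTTTATTGGGCTC,47.37,0,1,oHBvRPOIvGrv5iFlbCBF_20000101000000.html
clone_002,GACTGGCCGAATAGGGATA,TATCCCTATTCGGCCAGTC,52.63,1,1,NOgmBjMtpsiaOclRz3Aw_20000101000000.html
clone_003,GAGGCAACGACATGTGCGG,CCGCACATGTCGTTGCCTC,63.16,2,1,zKsbVRJN9wVGFYGW2WmQ_20000101000000.html
clone_004,GGACCCTTGCGACAGTGAC,GTCACTGTCGCAAGGGTCC,63.16,3,1,zCudiH7YFjS1on43XkMt_20000101000000.html
clone_005,GCTTTCGCCGTTGCCTAAA,TTTAGGCAACGGCGAAAGC,52.63,0,1,ECqOxSF2O3GYRdo1XKXW_20000101000000.html
```

One row per extracted siRNA: the passenger/guide duplex, its GC content,
the smallest mismatch level `k_used` at which a target was found (matching
each clone's planted distance), the number of distinct target genes at that
level, and the HTML page with the highlighted read, per-target alignments,
annotation links and significant expression profiles. With `--frozen-clock`
and a fixed `--seed` the whole bundle (CSV, HTML, zip) is byte-reproducible.

A single sequence can be searched directly:

```bash
shrnascan search GACTGGCCGAATAGGGATA --db demo/transcripts.fasta
```

```
accession	gene	position	mismatches	window	edit
NM_100014.1	GENE14	735	1	GACTGGCCGAATAGGGTTA	16=1X2=
```

(positions are 1-based in exports; `16=1X2=` reads as 16 matches, one
substitution, two matches).

From Python:

```python
from shrnascan import (parse_pattern, extract_sirna, load_database,
                       build_index, resolve_query)

pattern = parse_pattern("tatagaaaaaa(.{ 19 })")
(duplex,) = extract_sirna(("clone1", read_sequence), pattern)
index = build_index(load_database("refseq_mrna.fasta"), query_length=19)
result = resolve_query(duplex, index)
print(result.k_used, result.n_target_genes, result.target_genes)
```

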