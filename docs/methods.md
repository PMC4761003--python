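# Methods

## Problem setting

An shRNA expression cassette encodes the siRNA stem as an inverted repeat:
vector sequence, sense (passenger) 19-mer, loop, antisense (guide) 19-mer.
After screening a random-oligonucleotide RNAi library, each recovered clone
is sequenced and the embedded siRNA must be mapped to candidate target
mRNAs. Because silencing tolerates a few substitutions, candidates are
sought not only at exact identity but at Hamming distance up to 3, taking
the *smallest* distance with any hit as the clone's mismatch level.
`shrnascan` implements that analysis offline, plus the downstream steps a
screener needs: display alignments, gene annotation links, differential
expression context, and archivable reports.

## Sequence model and extraction

All sequences are normalized to uppercase DNA (U→T), so published siRNA
strands written as RNA are accepted unchanged. The pattern grammar is a
literal flank plus a single fixed-length capture `(.{N})` (whitespace inside
the braces tolerated, matching the printed form of the web-form default);
an empty pattern means the whole input is the siRNA, a bare capture means
its first N bases are. Flank matching is exact: the flank is vector
sequence, identical in every clone, so mismatch-tolerant flank search would
only admit sequencing errors into the capture.

The read and its reverse complement are both scanned; forward matches
(left to right) are reported before reverse ones, and all matches are
reported (the first is primary in CLI output). Capture coordinates are
0-based half-open on the input read as given, mapped back through the
orientation flip; reports print 1-based positions. An `N` inside a captured
window flags the duplex rather than failing the read; flagged duplexes are
excluded from search by default because Hamming distance against `N` is not
meaningful (overridable).

One grammar choice was genuinely open: a capture with a trailing but no
leading flank. We treat any pattern with at least one non-empty flank as
flanked mode (scanning backwards from trailing-flank matches), and reserve
prefix-capture mode for a bare capture group; otherwise trailing-only
patterns would be unreachable.

## k-mismatch search

Matching is substitution-only. Gapped similarity is deliberately out of
scope: the mismatch level reported per clone counts substitutions, and an
indel between an siRNA and a target would change the silencing register
entirely.

The index uses the pigeonhole principle: for queries of length L with up to
k mismatches, the query is split into k+1 disjoint seeds (lengths
⌊L/(k+1)⌋, remainder distributed to the trailing seeds: 4+5+5+5 for L=19,
k=3). Any window within k substitutions must match at least one seed
exactly, so candidate windows are collected from a hash table of every
seed-slot substring and verified by direct comparison with early exit.
Each transcript is scanned independently (no concatenation tricks, so no
phantom windows across record boundaries). A window position is verified at
most once per query; hits are sorted by (mismatches, accession, position)
for byte-stable output. `N` in a window counts as a mismatch at that
position against every base, including `N`.

`naive_hamming_scan` — a vectorised scan of every window of every record —
is kept in the package as an independent reference implementation; the test
suite requires exact agreement between the two routes on seeded fixtures
(100 queries × 4 distance levels against 200 transcripts).

Escalation returns the hits at the smallest distance in [k_min, k_max] with
a non-empty exact-distance set; fixed-level search (`search_at_most`) is
exposed separately, so both printed search conditions are available. Target
counts collapse transcripts to distinct gene symbols per distance level
(isoforms of one gene count once); a gene appears at every level where it
has a hit. Gene symbols default to the last parenthesized token before
", mRNA" in a RefSeq-style definition line, with an accession→symbol TSV
taking precedence and the accession itself as fallback. Only plus strands
are searched, because the query is passenger-sense and therefore identical
in sense to the mRNA; guide-mode input is converted to its passenger before
searching.

## Alignments

`smith_waterman` is a standard local dynamic program with linear gap
penalty; defaults match +2, mismatch −1, gap −2 (the aligner's parameters
are a display choice — no published values exist for this step — and are
configurable and labelled in reports). Traceback ties prefer diagonal, then
up (gap in subject), then left; among equal end cells the first in
row-major order wins. The implementation is cross-checked against an
independently coded DP on random pairs.

Hits from the Hamming search are displayed with `window_alignment`, the
full-window gapless alignment, *not* the unconstrained local optimum. The
distinction matters: a strictly local alignment trims a terminal mismatch
(dropping its penalty raises the score) and can tie with gapped co-optima,
so its substitution count would not always equal the hit's verified
mismatch level. The full-window form shows exactly the substitutions the
search counted; with the default scoring its column-sum score is ≥ 29 for
any ≤3-mismatch 19-mer pair.

## Expression analysis

A DataSet is a gene × sample matrix whose samples are grouped into labelled
subsets by one experimental variable, with an organism and a source URL.
Selection keeps datasets that (i) match the organism, (ii) define exactly
two subsets under the one variable, and (iii) have at least
`min_samples_per_subset` samples per subset. The replicate floor defaults
to 3 — the strict reading of "more than two samples per condition" — and is
a parameter because the permissive reading (≥2) is also defensible.
Datasets with more than two groups are excluded rather than pairwise-tested.

Welch's t-statistic is computed from sample means and ddof-1 variances,
with Welch–Satterthwaite degrees of freedom (non-integer) and a two-sided
p-value from the t distribution. Degenerate inputs follow documented
conventions: both groups constant with equal means → t=0, p=1; both
constant with unequal means → p=0, flagged. A gene is "significant" in a
dataset at raw two-sided P < alpha (default 0.01); **no multiple-testing
correction is applied** — the flag marks per-dataset evidence, not a
familywise claim, so across many datasets ~1% of null genes are flagged by
construction. Values are tested as stored; whether they are log-scale is
carried as metadata only, since expression platforms differ and silent
transformation would be worse than none.

Calibration note: the exact size of Welch's test at n=5 per group on normal
data is ≈0.0075 at nominal alpha=0.01 (the estimated df makes the test
conservative at small n). Null-simulation flag rates around 0.007–0.008 at
that sample size therefore reflect the test itself, not an implementation
bias — the implementation agrees with an independent reference routine to
better than 1e-10 in t, df and p.

## Annotation

Live database lookups are replaced by a local TSV (symbol, pipe-separated
synonyms, and id lists for GO, OMIM, PubMed, miRTarBase, REACTOME, HPRD)
plus URL templates with an `{id}` slot (built-in defaults, overridable via
a flat `name=template` file). Lookup is case-insensitive and synonym-aware,
and total: unknown symbols yield an empty annotation with no links rather
than an error. Links are emitted only for non-empty id lists; the HGNC link
is keyed by the symbol itself for known genes. `profile_counts` summarises,
per gene, the number of stored GO terms and the number of selected datasets
in which the gene is significantly differential — the two quantities used
to compare the annotation profiles of different target-gene sets.

## Reports

The summary table is RFC-4180 CSV (CRLF, minimal quoting; `--tsv` switches
the delimiter) with columns query_name, passenger, guide, gc_percent,
k_used, n_target_genes, html_file_name; `k_used` is `none` for no-target
queries and `error` for failed ones. HTML pages are static, script-free and
self-contained (inline CSS, no external fetches), so an archived page
renders anywhere. Result names are 20 characters drawn from the 62-symbol
alphanumeric alphabet plus a `YYYYMMDDhhmmss` timestamp; collisions are
regenerated with bounded retries. Zip entries are written with timestamps
taken from the run clock, so a seeded random source plus a frozen clock
reproduce the archive byte for byte.

## Synthetic fixtures

The generators define the conditions under which the pipeline is validated:

* **Transcriptome** — 200 transcripts of 1000–2000 nt at GC 0.5 by default,
  ~10% of them `XM_` decoys that the curated-record filter must drop.
  Planted sites are made by substituting exactly *d* positions of a query
  (d ∈ 0..3) at non-overlapping random loci of NM_ records. After planting,
  the background is scrubbed: any window within distance 3 of any planted
  query that is not a truth-table site is point-mutated (outside planted
  intervals) until none remain, bounded at 50 passes. The scrub makes truth
  tables exhaustive so recovery is scored exactly; it is a fixture
  property, not a claim about real transcriptomes, where near-neighbour
  windows certainly occur.
* **Clone reads** — pad + flank (`TATAGAAAAAA`) + passenger + loop
  (`TTCAAGAGA`, a common stem loop used purely as a constant) + antisense
  + pad, with every other read reverse-complemented. Library-shaped query
  sets are G-initiated 19-mers (pol III transcripts start with a purine; G
  is the library convention).
* **DataSets** — gaussian values (mean 8, SD 1); planted genes shifted by
  `effect_size` (default 3) SD in the second condition of every passing
  dataset; three deliberate violators (wrong organism, three subsets, a
  two-sample subset) accompany each collection so the selection rules are
  testable against truth. At the default effect size and n=5 per group the
  per-dataset detection power at alpha=0.01 is ~0.82.

Everything is driven by one seed (Python `random` for sequences, numpy
default_rng for values); identical seeds give byte-identical FASTA/TSV
output. What passing tests on these fixtures do **not** show: performance
or specificity on a real transcriptome (paralogs, repeats, isoform
redundancy), microarray noise beyond i.i.d. gaussians, or sequencing-error
handling in clone reads.

## Problem sizes and numerical choices

The validation suite runs the index/oracle equivalence at 200 transcripts ×
100 queries × 4 levels, planted recovery over 40 sites, orientation
invariance over 100 reads, alignment checks over 500 random pairs, Welch
calibration over 10,000 null pairs plus 1,000 reference comparisons —
sizes at which every check completes in seconds while the statistical
bands (3σ binomial) are tight. Determinism choices worth knowing: hit
ordering is (mismatches, accession, position); duplicate (accession,
position) pairs are reported once; equal-scoring alignment end cells
resolve to the first in row-major order; the per-query index is built per
distinct query length (whole-sequence mode can mix lengths).

## Limitations

* Hamming-only candidate search; gapped off-targets are invisible by design.
* Seed table is in-memory and rebuilt per run — appropriate for mRNA-scale
  databases, not genomes (no suffix-array/FM-index scale-out).
* Minus-strand matches are reachable only by reverse-complementing the
  query upstream.
* Raw per-dataset P-values; users needing familywise control must correct
  downstream.
* The annotation join is presentation, not inference: no ontology
  traversal or enrichment.
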