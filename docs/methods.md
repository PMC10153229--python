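# Methods

## Coordinate and identity conventions

All internal coordinates are 0-based half-open; the single conversion
from GTF's 1-based closed convention happens in `txcompare.gtf`. The
identity of every structural element — boundary, junction, intron
chain — includes chromosome **and** strand, so features at identical
coordinates on opposite strands never match. This is a deliberate
choice: cross-strand coordinate coincidences are biologically spurious
for splicing structure. Annotations with unreliable strand calls can be
compared with `ignore_strand` (CLI `--ignore-strand`), which collapses
all strands to `"."` before comparison.

Single-exon transcripts have no introns and therefore contribute nothing
to the boundary, junction or chain sets; gene correspondence is
restricted to genes with at least one multi-exon transcript for the same
reason. Adjacent exons with a zero-length gap are treated as a
validation error rather than silently merged — assembler and annotation
GTFs should not contain them, and silent merging would hide upstream
bugs. `--merge-adjacent` opts into the repair.

## Structural similarity

Annotation similarity is plain Jaccard over the three element sets.
When both sets at a level are empty (e.g. chain similarity of two
single-exon-only annotations) the value is reported as *undefined*
(`None`/`NA`), not 0 or 1: a fabricated value at either extreme would
misrepresent annotations that simply have no multi-exon structure to
compare.

## Gene correspondence

Two multi-exon genes across annotations form a pair when they share at
least one intron–exon boundary. The definitional alternative — requiring
a whole shared junction — is strictly stricter and is exposed as
`pair_on="junctions"`; boundary sharing is the default because a shared
donor or acceptor already evidences a shared splice site even when the
partner site differs. One gene may pair with several genes on the other
side; no greedy resolution is applied, since within one annotation genes
rarely share boundaries and multi-pairing is informative when it occurs.
Pairing is computed with a boundary→gene inverted index; a brute-force
all-pairs scan serves as the test oracle.

## Intron-retention detection

A transcript `t` is flagged against a same-assembly reference `r` when
`p(r)/p(t)` is **strictly** above `ratio_threshold` (default 0.5 — the
literal reading of "above"; the boundary case ratio = threshold does not
flag) and one of the three geometric criteria holds. Design choices:

- *First/last exon* means genomically leftmost/rightmost regardless of
  strand; the criteria mirror each other under strand flip, which keeps
  minus-strand behavior unambiguous.
- *Spans* requires ≥ `min_overlap_bases` (default 1) of overlap on each
  side of the crossed boundary — the weakest reading consistent with the
  definition; stricter variants are a parameter, not a fork.
- `t` and `r` must lie on the same strand by default
  (`require_same_strand`), since retention is a splicing event within
  one locus; `--allow-cross-strand` relaxes this.
- Criterion 3 includes exact equality (an exon coinciding with the
  intron counts as full coverage).
- A single-exon `t` is allowed: its sole exon is both first and last,
  so all three criteria are evaluated — an unspliced pre-mRNA fragment
  is the canonical retained-intron artifact.
- The criteria are evaluated independently and may co-fire; every
  `(t, r, criterion)` combination is reported, and "flagged" is the
  existential reduction over a transcript's calls.
- Transcripts with zero abundance are skipped as queries with a warning
  (their ratio is undefined) rather than treated as always-flaggable.
- `ignore_abundance` disables the ratio gate entirely, for assemblies
  lacking abundance attributes; otherwise a missing abundance is an
  error.

Detection uses a per-chromosome interval tree over transcript spans; an
intentionally naive all-pairs re-evaluation (`fixtures.brute_force_ir`,
no shared code) is the oracle in tests.

## Assembly evaluation

Multi-exon matching is exact intron-chain identity. Single-exon
matching uses **reciprocal** overlap: the shared length must be at least
the threshold fraction (default 0.8) of *both* transcripts' lengths.
Reciprocal overlap is symmetric and the threshold is configurable to
emulate one-sided variants. Among multiple match candidates the first
by (chrom, start, id) is reported, for determinism. Duplicate chains in
an assembly each count toward `#assembled` and `#matching` — the metric
counts assembled transcripts, not unique chains — with `--dedup-chains`
available to collapse them.

Adjusted precision removes the currently lowest-abundance transcript
(ties broken lexically by id) until the matching count equals the
target. Because matching is against a fixed reference, removals change
counts but never other transcripts' match status, so the loop terminates
with the matching count exactly at target (asserted). The operation
takes the target count as an argument; orchestrating the two-assembly
comparison lives in the CLI (`eval-adjusted`).

## Synthetic data

`random_annotation` emulates annotation/assembly structure: genes placed
non-overlapping along a chromosome, each with a multi-exon backbone
(exon lengths 50–300 bp, intron lengths 60–2000 bp, up to 8 exons);
isoforms keep each backbone junction with probability 0.8 (dropping a
junction merges the flanking exons), jitter terminal exon extents, and
are single-exon with probability 0.1; abundances are log-uniform over
0.1–100, spanning the dynamic range of transcript-level expression
estimates. These defaults make isoforms of one gene share most
junctions while differing in chains and termini, which is the regime
the similarity and pairing metrics target.

`plant_ir` grafts transcripts engineered to satisfy exactly one
retention criterion against a chosen reference, with abundance set so
the ratio gate passes (ratio drawn in [1, 5]) — or, with
`pass_ratio_gate=False`, set high enough that no transcript in the
assembly can reference it. Ground truth is returned for recovery tests;
planted events are recovered with zero false negatives, while false
positives can only arise from incidental geometry between pre-existing
transcripts.

What the generator does **not** emulate: read-level noise, soft-clipped
or misassembled exon boundaries, overlapping gene loci, multi-chromosome
genomes, realistic expression models, or annotation-scale transcript
counts. Passing tests therefore demonstrate correctness of the set
algebra, geometry and bookkeeping — not performance claims on real
annotations, whose scale and messiness are handled by the same code
paths but validated only structurally here.

The two hand-built toy instances pin known outcomes: a pair of
annotations with similarity exactly 5/6, 5/8 and 1/3 at the boundary,
junction and chain levels (realised with 10-of-12 boundaries, 5-of-8
junctions and 1-of-3 chains — the smallest boundary-set realisation
consistent with 5 shared junctions, since five strictly-ordered shared
junctions already require ten shared endpoint positions), and a
four-isoform assembly whose transcripts t2/t3/t4 trigger exactly
criteria 1/2/3 against the abundant isoform t1.

## Numerical and degenerate-input choices

- Empty assembly: precision undefined (`None`), `#assembled = 0`.
- Both-empty set at a similarity level: value undefined, never 0 or 1.
- GTF attribute parsing is best-effort: duplicate keys keep the first
  occurrence, unquoted values and a missing trailing semicolon are
  tolerated, malformed lines are logged and skipped. Abundance is taken
  from the first present key of `TPM, FPKM, cov` (documented, ordered
  choice preferring normalised units) at the `transcript` feature, with
  exon-feature attributes as fallback.
- Floats written to GTF use `repr`, so abundance round-trips exactly.
- CLI exit codes: 0 success; 1 user error (missing file, invalid
  threshold range, malformed input); 2 internal error. Argument-syntax
  errors are reported by the option parser with its native status 2.

## Problem sizes

The test suite and the acceptance script run on seeded synthetic
annotations of up to ~50 transcripts per assembly — hundreds to a
thousand assemblies per property — chosen so that the brute-force
oracles (quadratic in transcripts, times exon×intron combinations)
remain the comparison baseline at every trial while the whole suite
completes in seconds.

## Known limitations

- GFF3 is not parsed; RefSeq users should supply the GTF distribution.
- Gene grouping trusts the `gene_id` attribute verbatim; there is no
  positional gene inference.
- Recall against an expressed-truth set is out of scope (unknown on
  real data); `#matching` is the recall proxy.
- Retention detection is purely structural + abundance-ratio based; it
  does not quantify retention from read coverage (no PSI/IR-ratio).
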