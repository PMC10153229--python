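# txcompare

Structural comparison of transcript annotations and intron-retention
filtering for RNA-seq transcript assemblies.

Reference-based assemblers (StringTie, Scallop, ...) are routinely scored
against a transcriptome annotation — but Ensembl, RefSeq and CHM13
annotations of the same genome disagree substantially, and assemblies are
contaminated by incompletely spliced pre-mRNA that surfaces as transcripts
with (partially) retained introns. `txcompare` gives bench and methods
scientists in transcriptomics the pieces needed to reason about both
problems: quantify how similar two annotations really are, build a gene
correspondence between them, evaluate an assembly against an annotation at
the transcript level, and detect or filter out intron-retention
transcripts using only the assembly itself.

## The model

For a transcript *t* with exons `e_1 < e_2 < ... < e_n` (0-based half-open
internally; GTF I/O converts once), define

- **B(t)** — the set of intron–exon boundaries: the donor and acceptor
  position of every intron (transcript termini are not boundaries);
- **J(t)** — the set of junctions: each intron as a `(donor, acceptor)` pair;
- **C(t)** — the intron chain: the ordered tuple of all junctions.

Gene- and annotation-level sets are unions, e.g. `B(g) = ∪_{t∈g} B(t)` and
`B(T) = ∪_{g∈T} B(g)`. Two annotations are compared with Jaccard
similarity at each level:

```
J_B(T1,T2) = |B(T1) ∩ B(T2)| / |B(T1) ∪ B(T2)|
```

and likewise `J_J` and `J_C`. Gene pairs across two annotations are formed
whenever two multi-exon genes share at least one boundary, each pair
scored with its own three Jaccard values.

A transcript *t* with abundance *p(t)* has **intron retention** if some
transcript *r* in the same assembly has `p(r)/p(t) > 0.5` (configurable,
strict) and (1) the first exon of *t* spans an intron of *r* and the
following exon, or (2) the last exon of *t* spans an exon of *r* and the
following intron, or (3) an exon of *t* fully covers an intron of *r*.

Assembly evaluation follows the standard transcript-level rule: a
multi-exon transcript *matches* when its intron chain is identical to an
annotated one; a single-exon transcript matches on ≥80% reciprocal
overlap with a single-exon annotated transcript. Reported metrics are
`#matching` (a recall proxy) and `precision = #matching / #assembled`,
plus the *adjusted precision* that trims the higher-recall assembly's
lowest-abundance transcripts until the matching counts agree.

## Worked example

```
$ txcompare make-fixtures --seed 7 --out fx
$ txcompare anncompare fx/toy_annotation_1.gtf fx/toy_annotation_2.gtf
level	jaccard	n1	n2	n_shared	n_union
boundary	0.833333	12	10	10	12
junction	0.625	6	7	5	8
intron_chain	0.333333	2	2	1	3
```

The two toy annotations share 10 of 12 boundary positions
(`J_B = 5/6`), 5 of 8 junctions (`J_J = 5/8`) and 1 of 3 intron chains
(`J_C = 1/3`): structurally similar gene models can still disagree on
most full-length isoforms, which is why the three levels are reported
together.

```
$ txcompare ir detect fx/toy_ir_assembly.gtf
transcript_id	reference_id	criterion	abundance_ratio
t2	t1	1	1.66667
t3	t1	2	2
t4	t1	3	2.5
...
$ txcompare ir filter fx/toy_ir_assembly.gtf -o clean.gtf
```

In the toy assembly, `t1` is the abundant fully spliced isoform; `t2`,
`t3` and `t4` each trigger one retention criterion against it (ratios
10/6, 10/5 and 10/4, all above 0.5) and are removed by `ir filter`,
leaving only `t1`. Other subcommands: `genepairs` (gene correspondence
TSV), `eval` / `eval-adjusted` (assembly evaluation), `biotype-table`
(per-biotype chain sharing between annotations).

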