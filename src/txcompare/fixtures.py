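"""Synthetic annotations, planted retention events, and brute-force
oracles.

Everything here exists so the package is fully testable without
downloading genome annotations: :func:`random_annotation` emulates the
gene/transcript structure an assembler or annotation provides (isoforms
of one gene sharing most junctions, log-uniform abundances spanning the
dynamic range of expression estimates), :func:`plant_ir` grafts
transcripts engineered to satisfy exactly one retention criterion onto
an assembly and returns the ground truth, and :func:`brute_force_ir` is
a deliberately naive re-evaluation of the retention definition used
only as an independent oracle in tests.

The two ``toy_*`` constructors are small hand-built instances with
known expected outcomes: a pair of annotations whose structural
similarity is exactly 5/6, 5/8 and 1/3 at the boundary, junction and
chain levels, and a four-transcript assembly in which transcripts t2,
t3 and t4 each trigger exactly one of the three retention criteria
against the high-abundance isoform t1.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import random
from typing import Optional

from .model import AnnotationSet, GenomeInterval, TranscriptModel
from .retention import IRCall, IRParams

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FixtureParams:
    """Knobs of the random annotation generator.

    Exon and intron lengths are drawn uniformly from the given ranges
    (bases); abundances are log-uniform over ``abundance_range``, which
    spans three orders of magnitude as transcript-level TPM estimates
    typically do. ``shared_junction_prob`` is the chance that an
    isoform keeps each junction of its gene's backbone structure, so
    isoforms of one gene share most but not all junctions.
    ``single_exon_prob`` is the chance a transcript is generated as
    single-exon. ``ir_plant_rate`` is the per-gene probability that
    :func:`plant_ir` adds one engineered retention event.
    """

    seed: int = 0
    n_genes: int = 10
    max_transcripts_per_gene: int = 4
    max_exons: int = 8
    exon_len_range: tuple = (50, 300)
    intron_len_range: tuple = (60, 2000)
    shared_junction_prob: float = 0.8
    single_exon_prob: float = 0.1
    ir_plant_rate: float = 0.5
    abundance_range: tuple = (0.1, 100.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.exon_len_range, self.intron_len_range, self.abundance_range):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")
        for rate in (self.shared_junction_prob, self.single_exon_prob, self.ir_plant_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


def _log_uniform(rng: random.Random, lo: float, hi: float) -> float:
    return math.exp(rng.uniform(math.log(lo), math.log(hi)))


def random_annotation(params: FixtureParams = FixtureParams()) -> AnnotationSet:
    """A deterministic random annotation with non-overlapping genes.

    Each gene gets a multi-exon backbone; each isoform subsamples the
    backbone's junctions (dropping a junction merges the flanking
    exons) and jitters its terminal exon extents, so isoforms share
    junctions but differ in chains and termini.
    """
    rng = random.Random(params.seed)
    transcripts = []
    cursor = 1000
    for gi in range(params.n_genes):
        gene_id = f"G{gi + 1:04d}"
        strand = rng.choice("+-")
        n_exons = rng.randint(2, max(2, params.max_exons))
        exons = []
        pos = cursor
        for _ in range(n_exons):
            length = rng.randint(*params.exon_len_range)
            exons.append((pos, pos + length))
            pos += length + rng.randint(*params.intron_len_range)
        gene_end = exons[-1][1]
        n_tx = rng.randint(1, params.max_transcripts_per_gene)
        for ti in range(n_tx):
            tid = f"{gene_id}.T{ti + 1}"
            abundance = _log_uniform(rng, *params.abundance_range)
            if rng.random() < params.single_exon_prob:
                s, e = rng.choice(exons)
                tx_exons = [(s, e)]
            else:
                tx_exons = [list(exons[0])]
                for nxt in exons[1:]:
                    if rng.random() < params.shared_junction_prob:
                        tx_exons.append(list(nxt))
                    else:
                        tx_exons[-1][1] = nxt[1]  # drop junction: merge exons
                # jitter terminal extents without crossing a junction
                first, last = tx_exons[0], tx_exons[-1]
                first[0] = max(0, first[0] + rng.randint(-30, (first[1] - first[0]) // 2))
                last[1] = last[1] + rng.randint(-(last[1] - last[0]) // 2, 30)
                tx_exons = [tuple(e) for e in tx_exons]
            chrom = "chr1"
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=[GenomeInterval(chrom, s, e) for s, e in tx_exons],
                    abundance=round(abundance, 4),
                )
            )
        cursor = gene_end + rng.randint(5000, 20000)
    return AnnotationSet.from_transcripts(transcripts)


def plant_ir(
    assembly: AnnotationSet,
    params: FixtureParams = FixtureParams(),
    pass_ratio_gate: bool = True,
    ir_params: IRParams = IRParams(),
) -> tuple:
    """Graft engineered retention events onto an assembly.

    For each gene, with probability ``ir_plant_rate``, one multi-exon
    transcript with positive abundance is chosen as reference ``r`` and
    a new transcript is constructed to satisfy exactly one criterion
    against it: first exon starting inside an intron of ``r`` and
    ending inside the following exon (criterion 1); the mirror at the
    last exon (criterion 2); or two consecutive exons of ``r`` merged
    across their intron (criterion 3).

    With ``pass_ratio_gate`` the new transcript's abundance is set
    below ``r``'s so that p(r)/p(t) clears the threshold; otherwise it
    is set high enough that *no* transcript in the assembly can serve
    as its reference, so detection must stay silent.

    Returns ``(assembly_with_plants, truth)`` where ``truth`` maps each
    planted transcript id to its criterion set. Genes with no eligible
    reference are skipped with a log message.
    """
    rng = random.Random(params.seed + 7919)
    max_abundance = max(
        (t.abundance for t in assembly.transcripts.values() if t.abundance), default=1.0
    )
    out = [t.copy() for t in assembly.iter_transcripts()]
    truth: dict = {}
    for gene_id in sorted(assembly.genes):
        if rng.random() > params.ir_plant_rate:
            continue
        refs = [
            t
            for t in assembly.genes[gene_id].transcripts
            if t.is_multi_exon and (t.abundance or 0) > 0
        ]
        # criteria 1-2 need an intron with a following/preceding exon and
        # enough room for a mid-intron start; any >=2-exon ref qualifies
        refs = [r for r in refs if all(b - a >= 2 for a, b in _intron_pairs(r))]
        if not refs:
            logger.info("gene %s: no eligible reference, planting skipped", gene_id)
            continue
        r = rng.choice(sorted(refs, key=lambda t: t.transcript_id))
        criterion = rng.randint(1, 3)
        exons = _planted_exons(r, criterion, rng)
        if pass_ratio_gate:
            abundance = r.abundance * rng.uniform(0.2, 1.0)  # ratio in [1, 5]
        else:
            # nothing in the assembly reaches ratio_threshold against it
            abundance = (
                max_abundance * 2 / ir_params.ratio_threshold
                if ir_params.ratio_threshold > 0
                else max_abundance * 1e9
            )
        tid = f"{r.transcript_id}.ir{criterion}"
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=r.chrom,
                strand=r.strand,
                exons=[GenomeInterval(r.chrom, s, e) for s, e in exons],
                abundance=round(abundance, 6),
            )
        )
        truth[tid] = {criterion}
    return AnnotationSet.from_transcripts(out), truth


def _intron_pairs(t: TranscriptModel):
    return [(left.end, right.start) for left, right in zip(t.exons, t.exons[1:])]


def _planted_exons(r: TranscriptModel, criterion: int, rng: random.Random) -> list:
    introns = _intron_pairs(r)
    i = rng.randrange(len(introns))
    a, b = introns[i]
    mid = a + (b - a) // 2  # strictly inside the intron for b - a >= 2
    if criterion == 1:
        nxt = r.exons[i + 1]
        return [(mid, nxt.end)] + [(e.start, e.end) for e in r.exons[i + 2 :]]
    if criterion == 2:
        prev = r.exons[i]
        return [(e.start, e.end) for e in r.exons[:i]] + [(prev.start, mid)]
    merged = (r.exons[i].start, r.exons[i + 1].end)
    return (
        [(e.start, e.end) for e in r.exons[:i]]
        + [merged]
        + [(e.start, e.end) for e in r.exons[i + 2 :]]
    )


def brute_force_ir(assembly: AnnotationSet, params: IRParams = IRParams()) -> list:
    """Naive re-evaluation of the retention definition; test oracle only.

    Loops over all ordered transcript pairs and all exon x intron
    combinations with inline geometry — no interval index, no shared
    code with :func:`txcompare.retention.detect_ir`.
    """
    calls = []
    transcripts = sorted(assembly.transcripts.values(), key=lambda t: t.transcript_id)
    for t in transcripts:
        if not params.ignore_abundance:
            if t.abundance is None:
                raise ValueError(f"{t.transcript_id}: abundance required")
            if t.abundance == 0:
                continue
        for r in transcripts:
            if r.transcript_id == t.transcript_id or r.chrom != t.chrom:
                continue
            if params.require_same_strand and r.strand != t.strand:
                continue
            if t.exons[-1].end <= r.exons[0].start or r.exons[-1].end <= t.exons[0].start:
                continue
            if params.ignore_abundance:
                if r.abundance is None or t.abundance in (None, 0):
                    ratio = math.inf
                else:
                    ratio = r.abundance / t.abundance
            else:
                if r.abundance is None:
                    raise ValueError(f"{r.transcript_id}: abundance required")
                ratio = r.abundance / t.abundance
                if not ratio > params.ratio_threshold:
                    continue
            r_introns = [(x.end, y.start) for x, y in zip(r.exons, r.exons[1:])]
            mo = params.min_overlap_bases
            crit1 = crit2 = crit3 = False
            for idx, (a, b) in enumerate(r_introns):
                fs, fe = t.exons[0].start, t.exons[0].end
                ns, ne = r.exons[idx + 1].start, r.exons[idx + 1].end
                if (
                    min(fe, b) - max(fs, a) >= mo
                    and min(fe, ne) - max(fs, ns) >= mo
                ):
                    crit1 = True
                ls, le = t.exons[-1].start, t.exons[-1].end
                ps, pe = r.exons[idx].start, r.exons[idx].end
                if (
                    min(le, pe) - max(ls, ps) >= mo
                    and min(le, b) - max(ls, a) >= mo
                ):
                    crit2 = True
                for e in t.exons:
                    if e.start <= a and b <= e.end:
                        crit3 = True
            for crit, hit in ((1, crit1), (2, crit2), (3, crit3)):
                if hit:
                    calls.append(IRCall(t.transcript_id, r.transcript_id, crit, ratio))
    calls.sort(key=lambda c: (c.t_id, c.r_id, c.criterion))
    return calls


def toy_annotation_pair() -> tuple:
    """Two tiny annotations with known structural similarity.

    Both contain a transcript with the shared four-junction chain; each
    adds a second transcript with a private chain. By construction the
    Jaccard similarities are exactly 10/12 = 5/6 (boundary), 5/8
    (junction) and 1/3 (intron chain).
    """

    def tx(tid, gid, exons, abundance=None):
        return TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom="chr1",
            strand="+",
            exons=[GenomeInterval("chr1", s, e) for s, e in exons],
            abundance=abundance,
        )

    shared = [(50, 100), (200, 300), (400, 500), (600, 700), (800, 850)]
    t1 = AnnotationSet.from_transcripts(
        [
            tx("T1.a", "A1", shared),
            tx("T1.b", "A1", [(850, 900), (1000, 1100), (1200, 1250)]),
        ]
    )
    t2 = AnnotationSet.from_transcripts(
        [
            tx("T2.a", "B1", shared),
            tx("T2.b", "B1", [(50, 100), (400, 500), (800, 900), (1000, 1050)]),
        ]
    )
    return t1, t2


def toy_ir_assembly() -> AnnotationSet:
    """Four-isoform assembly with one retention event per criterion.

    t1 is the abundant, fully spliced isoform. t2's first exon starts
    inside t1's second intron and reaches into the following exon
    (criterion 1); t3's last exon extends from an exon of t1 into the
    next intron (criterion 2); t4 retains t1's second intron entirely
    inside its second exon (criterion 3).
    """

    def tx(tid, exons, abundance):
        return TranscriptModel(
            transcript_id=tid,
            gene_id="G1",
            chrom="chr1",
            strand="+",
            exons=[GenomeInterval("chr1", s, e) for s, e in exons],
            abundance=abundance,
        )

    return AnnotationSet.from_transcripts(
        [
            tx(
                "t1",
                [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000), (1100, 1200)],
                10.0,
            ),
            tx("t2", [(450, 600), (700, 800), (900, 1000)], 6.0),
            tx("t3", [(300, 400), (500, 600), (700, 850)], 5.0),
            tx("t4", [(100, 200), (300, 600), (700, 800)], 4.0),
        ]
    )
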