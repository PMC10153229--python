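"""Assembly-vs-annotation evaluation at the transcript level.

An assembled multi-exon transcript "matches" the reference annotation
when its intron chain (chromosome, strand, full junction tuple) is
identical to that of some annotated transcript — terminal exon extents
are ignored. An assembled single-exon transcript matches when it
reciprocally overlaps a single-exon annotated transcript by at least a
threshold fraction (default 0.8) of *both* transcripts' lengths.

From the per-transcript matches follow the two headline metrics:
``num_matching`` (proportional to recall when the annotation is treated
as truth) and ``precision = num_matching / num_assembled``. When two
assemblies trade off recall against precision, the *adjusted precision*
makes them comparable: the higher-recall assembly has its
lowest-abundance transcripts removed one by one until its matching
count equals the other's, and the precision at that point is compared.

Biotype-stratified views count matches within the annotation's
functional categories (protein_coding, retained_intron, lncRNA, ...).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from intervaltree import IntervalTree

from .model import AnnotationSet, TranscriptModel, chain_of

UNLABELED = "unlabeled"


@dataclasses.dataclass
class MatchResult:
    """Per-transcript matches plus the two summary metrics.

    ``precision`` is ``None`` (undefined) for an empty assembly.
    """

    matches: dict  # t_id -> matched reference transcript id, or None
    num_matching: int
    num_assembled: int
    precision: Optional[float]


@dataclasses.dataclass
class BiotypeTable:
    """Per-biotype (reference chain count, matched chain count) rows."""

    rows: dict  # biotype -> (n_reference, n_matched)

    def percentage(self, biotype: str) -> float:
        n_ref, n_matched = self.rows[biotype]
        return 100.0 * n_matched / n_ref if n_ref else 0.0


class ReferenceIndex:
    """Reference annotation indexed for transcript-level matching:
    intron chain -> transcripts, and an interval tree over single-exon
    transcripts per chromosome/strand."""

    def __init__(self, ref: AnnotationSet):
        self.chains: dict = {}
        self.single_exon: dict = {}
        for t in ref.transcripts.values():
            chain = chain_of(t)
            if chain is not None:
                self.chains.setdefault(chain, []).append(t)
            else:
                key = (t.chrom, t.strand)
                self.single_exon.setdefault(key, IntervalTree()).addi(t.start, t.end, t)
        for cands in self.chains.values():
            cands.sort(key=_tie_key)


def _tie_key(t: TranscriptModel):
    return (t.chrom, t.start, t.transcript_id)


def match_transcript(
    t: TranscriptModel,
    ref,
    single_exon_min_overlap: float = 0.8,
) -> Optional[str]:
    """Id of the reference transcript matched by ``t``, or ``None``.

    ``ref`` may be an :class:`AnnotationSet` or a prebuilt
    :class:`ReferenceIndex`. Among multiple candidates the first by
    (chrom, start, id) is reported.
    """
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    chain = chain_of(t)
    if chain is not None:
        cands = index.chains.get(chain)
        return cands[0].transcript_id if cands else None
    tree = index.single_exon.get((t.chrom, t.strand))
    if tree is None:
        return None
    hits = []
    for iv in tree.overlap(t.start, t.end):
        r = iv.data
        ov = min(t.end, r.end) - max(t.start, r.start)
        if (
            ov >= single_exon_min_overlap * (t.end - t.start)
            and ov >= single_exon_min_overlap * (r.end - r.start)
        ):
            hits.append(r)
    if not hits:
        return None
    return min(hits, key=_tie_key).transcript_id


def evaluate(
    assembly: AnnotationSet,
    ref: AnnotationSet,
    single_exon_min_overlap: float = 0.8,
    dedup_chains: bool = False,
) -> MatchResult:
    """Match every assembled transcript against the reference.

    Duplicate chains within the assembly each count separately (an
    assembler emitting a transcript twice is counted twice);
    ``dedup_chains`` collapses them to the first by (chrom, start, id)
    before counting.
    """
    index = ReferenceIndex(ref)
    transcripts = list(assembly.iter_transcripts())
    if dedup_chains:
        seen: dict = {}
        for t in sorted(transcripts, key=_tie_key):
            key = chain_of(t) or ("single", t.chrom, t.strand, t.start, t.end)
            seen.setdefault(key, t)
        transcripts = sorted(seen.values(), key=lambda t: t.transcript_id)
    matches = {
        t.transcript_id: match_transcript(t, index, single_exon_min_overlap)
        for t in transcripts
    }
    num_matching = sum(1 for m in matches.values() if m is not None)
    num_assembled = len(matches)
    precision = num_matching / num_assembled if num_assembled else None
    return MatchResult(matches, num_matching, num_assembled, precision)


def adjusted_precision(
    assembly: AnnotationSet,
    ref: AnnotationSet,
    target_matching: int,
    single_exon_min_overlap: float = 0.8,
) -> float:
    """Precision after trimming the assembly down to a target recall.

    Repeatedly removes the transcript with the lowest abundance (ties
    broken by transcript_id) until the matching count equals
    ``target_matching``, then returns matching/remaining. Requires the
    assembly's matching count to start at or above the target and every
    transcript to carry an abundance.
    """
    if target_matching < 0:
        raise ValueError("target_matching must be >= 0")
    result = evaluate(assembly, ref, single_exon_min_overlap)
    if result.num_matching < target_matching:
        raise ValueError(
            f"cannot reach target {target_matching}: assembly matches only "
            f"{result.num_matching}"
        )
    missing = [tid for tid in result.matches if assembly.transcripts[tid].abundance is None]
    if missing:
        raise ValueError(f"transcripts lack abundance: {missing[:5]}")

    order = sorted(
        result.matches,
        key=lambda tid: (assembly.transcripts[tid].abundance, tid),
    )
    num_matching = result.num_matching
    num_remaining = result.num_assembled
    removed = 0
    while num_matching > target_matching:
        tid = order[removed]
        removed += 1
        num_remaining -= 1
        if result.matches[tid] is not None:
            num_matching -= 1
    assert num_matching == target_matching
    if num_remaining == 0:
        raise ValueError("all transcripts removed before reaching target")
    return num_matching / num_remaining


def biotype_crosstab(ref_with_biotypes: AnnotationSet, other: AnnotationSet) -> BiotypeTable:
    """How many multi-exon reference chains of each biotype occur in ``other``.

    Reference transcripts are made unique by intron chain; two
    transcripts are considered the same when they share the same chain.
    Transcripts without a biotype group under "unlabeled".
    """
    other_chains = {
        c for c in (chain_of(t) for t in other.transcripts.values()) if c is not None
    }
    per_biotype: dict = {}
    for t in ref_with_biotypes.transcripts.values():
        chain = chain_of(t)
        if chain is None:
            continue
        per_biotype.setdefault(t.biotype or UNLABELED, set()).add(chain)
    rows = {
        biotype: (len(chains), sum(1 for c in chains if c in other_chains))
        for biotype, chains in sorted(per_biotype.items())
    }
    return BiotypeTable(rows)


def stratify_matches_by_biotype(
    assembly: AnnotationSet,
    ref_with_biotypes: AnnotationSet,
    single_exon_min_overlap: float = 0.8,
) -> dict:
    """Count matched assembled transcripts by the biotype of the
    reference transcript they match. Unmatched transcripts are not
    counted; matches to biotype-less references count as "unlabeled"."""
    result = evaluate(assembly, ref_with_biotypes, single_exon_min_overlap)
    counts: dict = {}
    for matched_id in result.matches.values():
        if matched_id is None:
            continue
        biotype = ref_with_biotypes.transcripts[matched_id].biotype or UNLABELED
        counts[biotype] = counts.get(biotype, 0) + 1
    return dict(sorted(counts.items()))


def exclusive_matches(
    assembly: AnnotationSet,
    ref_a: AnnotationSet,
    ref_b: AnnotationSet,
    single_exon_min_overlap: float = 0.8,
) -> dict:
    """Assembled transcripts matching ``ref_a`` but not ``ref_b``,
    counted by the ref_a biotype of the matched transcript."""
    index_b = ReferenceIndex(ref_b)
    result_a = evaluate(assembly, ref_a, single_exon_min_overlap)
    counts: dict = {}
    for tid, matched_id in result_a.matches.items():
        if matched_id is None:
            continue
        if match_transcript(assembly.transcripts[tid], index_b, single_exon_min_overlap):
            continue
        biotype = ref_a.transcripts[matched_id].biotype or UNLABELED
        counts[biotype] = counts.get(biotype, 0) + 1
    return dict(sorted(counts.items()))
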