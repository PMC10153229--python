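"""Detection and filtering of transcripts with (partial) intron retention.

A transcript ``t`` in an assembly is flagged as carrying a retained
intron by comparing it against every other transcript ``r`` of the same
assembly whose abundance is high enough to serve as a reference —
``p(r)/p(t)`` strictly above a threshold, 0.5 by default. Against such
an ``r``, three geometric criteria are tested:

1. the **first** exon of ``t`` spans an intron of ``r`` and the exon
   immediately following that intron (i.e. it crosses the acceptor
   boundary from inside the intron into the next exon);
2. the **last** exon of ``t`` spans an exon of ``r`` and the intron
   immediately following it (crosses the donor boundary);
3. some exon of ``t`` fully covers some intron of ``r``.

Criteria 1 and 2 capture *partial* retention at transcript termini —
the hallmark of fragments assembled from incompletely spliced
pre-mRNA — while criterion 3 captures full retention of an intron. One
transcript may satisfy several criteria, against the same or different
references; each (t, r, criterion) combination yields one
:class:`IRCall`, and a transcript is "flagged" when it has at least one
call.

"First"/"last" exon means genomically leftmost/rightmost regardless of
strand; by default ``t`` and ``r`` must lie on the same strand, since
retention is a splicing event within one locus. "Spans" requires at
least ``min_overlap_bases`` (default 1) of overlap on each side of the
crossed boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import math

from intervaltree import IntervalTree

from .model import AnnotationSet, TranscriptModel, introns_of

logger = logging.getLogger(__name__)


class AbundanceRequiredError(ValueError):
    """IR detection needs per-transcript abundances (or ignore_abundance)."""


class CallConsistencyError(ValueError):
    """A call references a transcript absent from the assembly."""


@dataclasses.dataclass(frozen=True)
class IRParams:
    """Detection parameters.

    ratio_threshold: p(r)/p(t) must be STRICTLY above this (default 0.5).
    require_same_strand: restrict references to t's strand (default on).
    min_overlap_bases: minimum overlap on each side of a crossed
        boundary for the "spans" tests of criteria 1-2 (default 1).
    ignore_abundance: disable the ratio gate entirely — every reference
        passes it; for assemblies without abundance attributes.
    """

    ratio_threshold: float = 0.5
    require_same_strand: bool = True
    min_overlap_bases: int = 1
    ignore_abundance: bool = False

    def __post_init__(self) -> None:
        if self.ratio_threshold < 0:
            raise ValueError(f"ratio_threshold must be >= 0, got {self.ratio_threshold}")
        if self.min_overlap_bases < 1:
            raise ValueError(f"min_overlap_bases must be >= 1, got {self.min_overlap_bases}")


@dataclasses.dataclass(frozen=True)
class IRCall:
    """One detected retention event: t flagged against reference r."""

    t_id: str
    r_id: str
    criterion: int  # 1, 2 or 3
    ratio: float  # p(r)/p(t); inf when abundance is ignored and absent


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _ratio(t: TranscriptModel, r: TranscriptModel, params: IRParams):
    """p(r)/p(t), or None if t must be skipped, under the params' policy."""
    if params.ignore_abundance:
        if t.abundance is None or r.abundance is None or t.abundance == 0:
            return math.inf
        return r.abundance / t.abundance
    if t.abundance is None or r.abundance is None:
        raise AbundanceRequiredError(
            f"transcript {t.transcript_id if t.abundance is None else r.transcript_id} "
            "has no abundance; re-run with ignore_abundance to skip the ratio gate"
        )
    if t.abundance == 0:
        return None
    return r.abundance / t.abundance


def candidate_references(
    t: TranscriptModel, assembly: AnnotationSet, params: IRParams = IRParams()
) -> list:
    """References eligible for testing ``t``: same chromosome (and
    strand, if required), overlapping genomic span, and abundance ratio
    strictly above the threshold. Sorted by transcript_id."""
    out = []
    for r in assembly.iter_transcripts():
        if _is_candidate(t, r, params):
            out.append(r)
    return out


def _is_candidate(t: TranscriptModel, r: TranscriptModel, params: IRParams) -> bool:
    if r.transcript_id == t.transcript_id:
        return False
    if r.chrom != t.chrom:
        return False
    if params.require_same_strand and r.strand != t.strand:
        return False
    if _overlap(t.start, t.end, r.start, r.end) <= 0:
        return False
    if params.ignore_abundance:
        return True
    ratio = _ratio(t, r, params)
    return ratio is not None and ratio > params.ratio_threshold


def check_criterion1(t: TranscriptModel, r: TranscriptModel, min_overlap_bases: int = 1) -> bool:
    """First exon of t spans an intron of r and the following exon of r."""
    first = t.exons[0]
    for i, intron in enumerate(introns_of(r)):
        nxt = r.exons[i + 1]
        if (
            _overlap(first.start, first.end, intron.donor, intron.acceptor) >= min_overlap_bases
            and _overlap(first.start, first.end, nxt.start, nxt.end) >= min_overlap_bases
        ):
            return True
    return False


def check_criterion2(t: TranscriptModel, r: TranscriptModel, min_overlap_bases: int = 1) -> bool:
    """Last exon of t spans an exon of r and the following intron of r."""
    last = t.exons[-1]
    for i, intron in enumerate(introns_of(r)):
        prev = r.exons[i]
        if (
            _overlap(last.start, last.end, prev.start, prev.end) >= min_overlap_bases
            and _overlap(last.start, last.end, intron.donor, intron.acceptor) >= min_overlap_bases
        ):
            return True
    return False


def check_criterion3(t: TranscriptModel, r: TranscriptModel, min_overlap_bases: int = 1) -> bool:
    """Some exon of t fully covers some intron of r (equality counts)."""
    introns = introns_of(r)
    for exon in t.exons:
        for intron in introns:
            if exon.start <= intron.donor and intron.acceptor <= exon.end:
                return True
    return False


_CRITERIA = ((1, check_criterion1), (2, check_criterion2), (3, check_criterion3))


def detect_ir(assembly: AnnotationSet, params: IRParams = IRParams()) -> list:
    """All retention calls in an assembly.

    Candidate references are found through a per-chromosome interval
    index on transcript spans; output is deterministic, sorted by
    (t_id, r_id, criterion). Transcripts with zero abundance are
    skipped with a warning (their reference ratio is undefined).
    """
    trees: dict = {}
    for r in assembly.transcripts.values():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    calls = []
    for t in assembly.iter_transcripts():
        if not params.ignore_abundance and t.abundance == 0:
            logger.warning(
                "transcript %s has zero abundance; skipped as query", t.transcript_id
            )
            continue
        hits = trees.get(t.chrom)
        if hits is None:
            continue
        refs = sorted(
            (iv.data for iv in hits.overlap(t.start, t.end)),
            key=lambda r: r.transcript_id,
        )
        for r in refs:
            if not _is_candidate(t, r, params):
                continue
            if not r.is_multi_exon:
                continue
            ratio = _ratio(t, r, params)
            for crit, check in _CRITERIA:
                if check(t, r, params.min_overlap_bases):
                    calls.append(IRCall(t.transcript_id, r.transcript_id, crit, ratio))
    calls.sort(key=lambda c: (c.t_id, c.r_id, c.criterion))
    return calls


def flagged_transcripts(calls) -> set:
    """Transcript ids with at least one retention call."""
    return {c.t_id for c in calls}


def split_assembly(assembly: AnnotationSet, calls) -> tuple:
    """Partition the assembly into (kept, removed) by the flagged set.

    ``removed`` holds every transcript with >= 1 call; ``kept`` the
    rest. The two outputs are disjoint and jointly exhaustive, with
    attributes and abundances preserved.
    """
    flagged = flagged_transcripts(calls)
    unknown = flagged - set(assembly.transcripts)
    if unknown:
        raise CallConsistencyError(
            f"calls reference transcripts not in the assembly: {sorted(unknown)}"
        )
    kept = AnnotationSet.from_transcripts(
        t for t in assembly.iter_transcripts() if t.transcript_id not in flagged
    )
    removed = AnnotationSet.from_transcripts(
        t for t in assembly.iter_transcripts() if t.transcript_id in flagged
    )
    return kept, removed
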