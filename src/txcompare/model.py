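"""In-memory models of transcripts, genes and annotations, and their
structural feature sets.

The structural identity of a multi-exon transcript is captured by three
nested abstractions, each a set of hashable elements so that annotations
can be compared with plain set algebra:

* **boundaries** ``B(t)`` — the genomic positions where an exon meets an
  intron (donor and acceptor ends of every intron). Transcript start/end
  positions are *not* boundaries.
* **junctions** ``J(t)`` — each intron as a ``(donor, acceptor)``
  coordinate pair.
* **intron chain** ``C(t)`` — the ordered tuple of all junctions; the
  conventional unit of transcript identity in assembly evaluation.

Gene- and annotation-level sets are unions over constituent transcripts.
Single-exon transcripts have no introns and therefore contribute to none
of the three sets.

All coordinates are 0-based half-open. GTF's 1-based closed convention is
converted exactly once at I/O time (see :mod:`txcompare.gtf`). Element
identity includes chromosome *and* strand: features on strand ``"."``
only ever equal other ``"."`` features. :func:`collapse_strands` erases
strand information when cross-strand identity is wanted.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, NamedTuple, Optional, Union

VALID_STRANDS = ("+", "-", ".")


class StructuralValidationError(ValueError):
    """Raised when an exon list violates the transcript-model invariants."""


class GenomeInterval(NamedTuple):
    """A genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class Boundary(NamedTuple):
    """An exon/intron transition position (donor or acceptor side)."""

    chrom: str
    strand: str
    position: int


class Junction(NamedTuple):
    """An intron as a (donor, acceptor) pair; donor < acceptor, half-open."""

    chrom: str
    strand: str
    donor: int
    acceptor: int


class IntronChain(NamedTuple):
    """The ordered tuple of all (donor, acceptor) pairs of a transcript."""

    chrom: str
    strand: str
    junctions: tuple  # tuple[tuple[int, int], ...], sorted by donor


@dataclasses.dataclass
class TranscriptModel:
    """One transcript: ordered exons plus optional abundance and biotype.

    Invariants (checked at construction): at least one exon; every exon a
    valid interval on the transcript's chromosome; exons sorted by start
    and separated by gaps of >= 1 base (each gap is an intron).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomeInterval]
    abundance: Optional[float] = None
    biotype: Optional[str] = None
    attributes: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise StructuralValidationError(
                f"{self.transcript_id}: invalid strand {self.strand!r}"
            )
        if not self.exons:
            raise StructuralValidationError(
                f"{self.transcript_id}: transcript has no exons"
            )
        self.exons = [GenomeInterval(*e) for e in self.exons]
        prev_end = None
        for ival in self.exons:
            if ival.chrom != self.chrom:
                raise StructuralValidationError(
                    f"{self.transcript_id}: exon on {ival.chrom}, "
                    f"transcript on {self.chrom}"
                )
            if ival.start < 0 or ival.start >= ival.end:
                raise StructuralValidationError(
                    f"{self.transcript_id}: bad exon interval "
                    f"({ival.start}, {ival.end})"
                )
            if prev_end is not None and ival.start - prev_end < 1:
                raise StructuralValidationError(
                    f"{self.transcript_id}: exons unsorted, overlapping or "
                    f"zero-gap at position {ival.start} (previous exon ends "
                    f"at {prev_end})"
                )
            prev_end = ival.end
        if self.abundance is not None and self.abundance < 0:
            raise StructuralValidationError(
                f"{self.transcript_id}: negative abundance {self.abundance}"
            )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomeInterval:
        """Genomic extent from first exon start to last exon end."""
        return GenomeInterval(self.chrom, self.start, self.end)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    def copy(self) -> "TranscriptModel":
        return TranscriptModel(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand=self.strand,
            exons=list(self.exons),
            abundance=self.abundance,
            biotype=self.biotype,
            attributes=dict(self.attributes),
        )


@dataclasses.dataclass
class GeneModel:
    """A gene: one or more transcripts sharing a gene_id."""

    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise StructuralValidationError(f"{self.gene_id}: gene has no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise StructuralValidationError(
                    f"gene {self.gene_id} contains transcript "
                    f"{t.transcript_id} with gene_id {t.gene_id}"
                )

    @property
    def has_multi_exon_transcript(self) -> bool:
        return any(t.is_multi_exon for t in self.transcripts)


@dataclasses.dataclass
class AnnotationSet:
    """A collection of genes with a flat transcript index.

    Every indexed transcript belongs to exactly one gene and transcript
    ids are unique across the annotation.
    """

    genes: dict = dataclasses.field(default_factory=dict)  # gene_id -> GeneModel
    transcripts: dict = dataclasses.field(default_factory=dict)  # t_id -> TranscriptModel

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "AnnotationSet":
        genes: dict = {}
        index: dict = {}
        for t in transcripts:
            if t.transcript_id in index:
                raise StructuralValidationError(
                    f"duplicate transcript_id {t.transcript_id}"
                )
            index[t.transcript_id] = t
            genes.setdefault(t.gene_id, []).append(t)
        return cls(
            genes={gid: GeneModel(gid, ts) for gid, ts in genes.items()},
            transcripts=index,
        )

    def iter_transcripts(self) -> Iterator[TranscriptModel]:
        """Transcripts in deterministic (transcript_id) order."""
        for tid in sorted(self.transcripts):
            yield self.transcripts[tid]

    @property
    def num_transcripts(self) -> int:
        return len(self.transcripts)

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        """New AnnotationSet restricted to the given transcript ids."""
        wanted = set(transcript_ids)
        missing = wanted - set(self.transcripts)
        if missing:
            raise KeyError(f"unknown transcript ids: {sorted(missing)}")
        return AnnotationSet.from_transcripts(
            self.transcripts[tid] for tid in sorted(wanted)
        )


@dataclasses.dataclass
class StructureSets:
    """The boundary/junction/chain sets of a transcript, gene or annotation."""

    boundaries: set = dataclasses.field(default_factory=set)
    junctions: set = dataclasses.field(default_factory=set)
    chains: set = dataclasses.field(default_factory=set)

    def update(self, other: "StructureSets") -> None:
        self.boundaries |= other.boundaries
        self.junctions |= other.junctions
        self.chains |= other.chains


def introns_of(t: TranscriptModel) -> list[Junction]:
    """The introns of ``t`` as junctions, in genomic order.

    A single-exon transcript has no introns and yields an empty list.
    """
    out = []
    for left, right in zip(t.exons, t.exons[1:]):
        out.append(Junction(t.chrom, t.strand, left.end, right.start))
    return out


def boundaries_of(t: TranscriptModel) -> set:
    """Donor and acceptor positions of every intron of ``t``.

    Cardinality is 2*(n_exons - 1) positions (before set collapse of
    coincident donors/acceptors, which cannot occur within one valid
    transcript). Transcript start/end are not boundaries.
    """
    out = set()
    for j in introns_of(t):
        out.add(Boundary(t.chrom, t.strand, j.donor))
        out.add(Boundary(t.chrom, t.strand, j.acceptor))
    return out


def chain_of(t: TranscriptModel) -> Optional[IntronChain]:
    """The intron chain of ``t``; ``None`` for single-exon transcripts.

    The chain ignores terminal exon extents: two transcripts that differ
    only in first-exon start or last-exon end have equal chains.
    """
    introns = introns_of(t)
    if not introns:
        return None
    return IntronChain(
        t.chrom, t.strand, tuple((j.donor, j.acceptor) for j in introns)
    )


Scope = Union[TranscriptModel, GeneModel, AnnotationSet]


def structure_sets(scope: Scope) -> StructureSets:
    """Boundary/junction/chain sets of a transcript, gene, or annotation.

    Gene and annotation scopes are set unions over their transcripts;
    duplicates collapse.
    """
    if isinstance(scope, TranscriptModel):
        sets = StructureSets()
        sets.boundaries = boundaries_of(scope)
        sets.junctions = set(introns_of(scope))
        chain = chain_of(scope)
        if chain is not None:
            sets.chains = {chain}
        return sets
    if isinstance(scope, GeneModel):
        transcripts: Iterable[TranscriptModel] = scope.transcripts
    elif isinstance(scope, AnnotationSet):
        transcripts = scope.transcripts.values()
    else:
        raise TypeError(f"unsupported scope type {type(scope).__name__}")
    sets = StructureSets()
    for t in transcripts:
        sets.update(structure_sets(t))
    return sets


def collapse_strands(annotation: AnnotationSet) -> AnnotationSet:
    """Copy of ``annotation`` with every strand set to ".".

    Used by the ``--ignore-strand`` mode: after collapsing, boundary,
    junction and chain identity no longer distinguishes strands.
    """
    out = []
    for t in annotation.iter_transcripts():
        c = t.copy()
        c.strand = "."
        c.exons = [GenomeInterval(e.chrom, e.start, e.end) for e in c.exons]
        out.append(c)
    return AnnotationSet.from_transcripts(out)
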