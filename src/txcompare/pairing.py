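"""Gene correspondence between two annotations.

Annotations disagree about where genes start and end and about how loci
are partitioned into genes, so gene names cannot anchor a comparison.
Instead, correspondence is built structurally: restricting both sides to
genes with at least one multi-exon transcript, a gene ``g1`` from one
annotation and ``g2`` from the other form a pair when they share at
least one intron-exon boundary. One gene may pair with several genes on
the other side (rare in practice, since genes within one annotation
seldom share boundaries); no greedy resolution is applied.

Each pair carries its own Jaccard similarity at the boundary, junction
and chain levels, computed over the two genes' structural sets.
"""

from __future__ import annotations

import dataclasses

from .model import AnnotationSet, collapse_strands, structure_sets


@dataclasses.dataclass
class GenePair:
    """A matched gene pair with its three per-pair Jaccard values."""

    gene1_id: str
    gene2_id: str
    j_boundary: float
    j_junction: float
    j_chain: float
    shared_boundary_count: int


def multi_exon_genes(annotation: AnnotationSet) -> AnnotationSet:
    """Genes having at least one multi-exon transcript.

    The filter is per-gene: a qualifying gene keeps *all* its
    transcripts, including single-exon ones.
    """
    keep = [
        t
        for gene in annotation.genes.values()
        if gene.has_multi_exon_transcript
        for t in gene.transcripts
    ]
    return AnnotationSet.from_transcripts(keep)


def pair_genes(
    t1: AnnotationSet,
    t2: AnnotationSet,
    pair_on: str = "boundaries",
    ignore_strand: bool = False,
) -> list:
    """All cross-annotation gene pairs sharing a structural element.

    ``pair_on`` selects the sharing criterion: ``"boundaries"`` (the
    default) pairs genes sharing an intron-exon boundary position;
    ``"junctions"`` requires a whole shared junction, a strictly
    stricter criterion. Pairing uses an element->gene inverted index
    rather than an all-pairs scan; output is sorted by (gene1, gene2).
    """
    if pair_on not in ("boundaries", "junctions"):
        raise ValueError(f"pair_on must be 'boundaries' or 'junctions', got {pair_on!r}")
    if ignore_strand:
        t1, t2 = collapse_strands(t1), collapse_strands(t2)
    g1s = multi_exon_genes(t1)
    g2s = multi_exon_genes(t2)
    sets1 = {gid: structure_sets(g) for gid, g in g1s.genes.items()}
    sets2 = {gid: structure_sets(g) for gid, g in g2s.genes.items()}

    key = "boundaries" if pair_on == "boundaries" else "junctions"
    index: dict = {}
    for gid, s in sets2.items():
        for elem in getattr(s, key):
            index.setdefault(elem, set()).add(gid)

    pairs = []
    for g1_id in sorted(sets1):
        s1 = sets1[g1_id]
        partners: set = set()
        for elem in getattr(s1, key):
            partners |= index.get(elem, set())
        for g2_id in sorted(partners):
            s2 = sets2[g2_id]
            shared_b = len(s1.boundaries & s2.boundaries)
            pairs.append(
                GenePair(
                    gene1_id=g1_id,
                    gene2_id=g2_id,
                    j_boundary=shared_b / len(s1.boundaries | s2.boundaries),
                    j_junction=_jacc(s1.junctions, s2.junctions),
                    j_chain=_jacc(s1.chains, s2.chains),
                    shared_boundary_count=shared_b,
                )
            )
    return pairs


def _jacc(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0
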