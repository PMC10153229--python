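"""Annotation-level structural similarity.

Two annotations are compared with Jaccard similarity at three levels of
structural resolution: intron-exon boundaries (J_B), splice junctions
(J_J), and complete intron chains (J_C). The three values are ordered in
practice — sharing a chain implies sharing all its junctions, and
sharing a junction implies sharing both its boundaries — so J_B >= J_J
>= J_C on typical annotation pairs, though the definitions are
independent set ratios.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Optional

from .model import AnnotationSet, collapse_strands, structure_sets


class LevelCounts(NamedTuple):
    """Cardinalities underlying one Jaccard value."""

    n1: int
    n2: int
    n_shared: int

    @property
    def n_union(self) -> int:
        return self.n1 + self.n2 - self.n_shared


@dataclasses.dataclass
class SimilarityReport:
    """The three Jaccard values plus their underlying set sizes.

    A value is ``None`` ("undefined") when both sets at that level are
    empty — e.g. chain similarity of two single-exon-only annotations.
    """

    j_boundary: Optional[float]
    j_junction: Optional[float]
    j_chain: Optional[float]
    boundary_counts: LevelCounts
    junction_counts: LevelCounts
    chain_counts: LevelCounts


def jaccard(set_a: set, set_b: set) -> Optional[float]:
    """|A ∩ B| / |A ∪ B|; ``None`` when both sets are empty.

    Elements must be structural features of the same level; mixing
    boundaries with junctions raises ``TypeError``.
    """
    types = {type(x) for x in set_a} | {type(x) for x in set_b}
    if len(types) > 1:
        raise TypeError(
            f"cannot mix structural levels: {sorted(t.__name__ for t in types)}"
        )
    union = len(set_a | set_b)
    if union == 0:
        return None
    return len(set_a & set_b) / union


def _level(set_a: set, set_b: set):
    counts = LevelCounts(len(set_a), len(set_b), len(set_a & set_b))
    value = None if counts.n_union == 0 else counts.n_shared / counts.n_union
    return value, counts


def compare_annotations(
    t1: AnnotationSet, t2: AnnotationSet, ignore_strand: bool = False
) -> SimilarityReport:
    """Jaccard similarity of two annotations at all three levels.

    ``ignore_strand`` collapses strands before comparing, so features at
    identical coordinates on opposite strands count as shared.
    """
    if ignore_strand:
        t1, t2 = collapse_strands(t1), collapse_strands(t2)
    s1, s2 = structure_sets(t1), structure_sets(t2)
    j_b, bc = _level(s1.boundaries, s2.boundaries)
    j_j, jc = _level(s1.junctions, s2.junctions)
    j_c, cc = _level(s1.chains, s2.chains)
    return SimilarityReport(
        j_boundary=j_b,
        j_junction=j_j,
        j_chain=j_c,
        boundary_counts=bc,
        junction_counts=jc,
        chain_counts=cc,
    )
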