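"""Transcript-level matching, precision, adjusted precision, biotypes."""

import pytest

from txcompare import (
    adjusted_precision,
    biotype_crosstab,
    evaluate,
    exclusive_matches,
    match_transcript,
    random_annotation,
    stratify_matches_by_biotype,
)
from txcompare.fixtures import FixtureParams

from conftest import make_annotation, make_transcript


REF_EXONS = [(100, 200), (300, 400), (500, 600)]


@pytest.fixture
def ref():
    return make_annotation(
        make_transcript("R1", REF_EXONS, gene_id="GR", biotype="protein_coding"),
        make_transcript("R2", [(1000, 1100), (1200, 1300)], gene_id="GR2", biotype="lncRNA"),
        make_transcript("RS", [(5000, 5100)], gene_id="GR3"),
    )


class TestMatching:
    def test_chain_match_ignores_terminal_extents(self, ref):
        longer = make_transcript("a", [(50, 200), (300, 400), (500, 700)])
        assert match_transcript(longer, ref) == "R1"

    def test_missing_junction_means_no_match(self, ref):
        partial = make_transcript("a", [(100, 200), (300, 400)])
        assert match_transcript(partial, ref) is None

    @pytest.mark.parametrize(
        "interval, expected",
        [
            ((4990, 5090), "RS"),   # overlap 90 >= 80% of both lengths (100, 100)
            ((5040, 5190), None),   # overlap 60 = 60% of each
            ((5000, 5100), "RS"),
        ],
    )
    def test_single_exon_reciprocal_overlap(self, ref, interval, expected):
        t = make_transcript("a", [interval])
        assert match_transcript(t, ref, single_exon_min_overlap=0.8) == expected

    def test_single_exon_asymmetric_containment(self):
        # overlap must clear the threshold on BOTH lengths
        ref = make_annotation(make_transcript("RS", [(10, 100)]))
        t = make_transcript("a", [(0, 100)])  # overlap 90: 90% of t, 100% of ref
        assert match_transcript(t, ref) == "RS"
        big = make_transcript("b", [(0, 200)])  # overlap 90: 45% of b
        assert match_transcript(big, ref) is None


class TestEvaluate:
    def test_self_evaluation(self, small_random):
        res = evaluate(small_random, small_random)
        assert res.precision == 1.0
        assert res.num_matching == res.num_assembled == small_random.num_transcripts

    def test_counts_and_precision(self, ref):
        asm = make_annotation(
            make_transcript("a1", REF_EXONS),                   # matches
            make_transcript("a2", [(1000, 1100), (1200, 1300)]),  # matches
            make_transcript("a3", [(100, 200), (300, 600)]),    # novel chain
            make_transcript("a4", [(7000, 7100)]),              # unmatched single-exon
        )
        res = evaluate(asm, ref)
        assert (res.num_assembled, res.num_matching) == (4, 2)
        assert res.precision == 0.5
        assert res.precision * res.num_assembled == res.num_matching

    def test_empty_assembly_precision_undefined(self, ref):
        res = evaluate(_empty(), ref)
        assert res.num_assembled == 0 and res.precision is None

    def test_duplicate_chains_count_separately(self, ref):
        asm = make_annotation(
            make_transcript("a1", REF_EXONS),
            make_transcript("a2", [(90, 200), (300, 400), (500, 610)]),
        )
        assert evaluate(asm, ref).num_matching == 2
        dedup = evaluate(asm, ref, dedup_chains=True)
        assert dedup.num_assembled == dedup.num_matching == 1

    def test_reference_monotone(self, ref, small_random):
        asm = make_annotation(make_transcript("a1", REF_EXONS))
        assert evaluate(asm, ref).num_matching == 1
        bigger = make_annotation(*ref.transcripts.values(), *small_random.transcripts.values())
        assert evaluate(asm, bigger).num_matching == 1


class TestAdjustedPrecision:
    def test_hand_derived_removal_sequence(self, ref):
        asm = make_annotation(
            make_transcript("m1", REF_EXONS, abundance=1.0),
            make_transcript("u1", [(100, 200), (300, 600)], abundance=2.0),
            make_transcript("m2", [(1000, 1100), (1200, 1300)], abundance=3.0),
        )
        assert adjusted_precision(asm, ref, target_matching=1) == pytest.approx(1 / 2)

    def test_target_equal_to_current_returns_precision(self, ref):
        asm = make_annotation(
            make_transcript("m1", REF_EXONS, abundance=1.0),
            make_transcript("u1", [(100, 200), (300, 600)], abundance=2.0),
        )
        assert adjusted_precision(asm, ref, target_matching=1) == pytest.approx(1 / 2)

    def test_all_matching_assembly_stays_perfect(self, ref):
        asm = make_annotation(
            make_transcript("m1", REF_EXONS, abundance=1.0),
            make_transcript("m2", [(1000, 1100), (1200, 1300)], abundance=2.0),
        )
        assert adjusted_precision(asm, ref, target_matching=1) == 1.0

    def test_unreachable_target_and_missing_abundance(self, ref):
        asm = make_annotation(make_transcript("m1", REF_EXONS, abundance=1.0))
        with pytest.raises(ValueError):
            adjusted_precision(asm, ref, target_matching=5)
        no_ab = make_annotation(make_transcript("m1", REF_EXONS))
        with pytest.raises(ValueError):
            adjusted_precision(no_ab, ref, target_matching=1)


class TestBiotypes:
    def test_crosstab_self_is_total(self, ref):
        table = biotype_crosstab(ref, ref)
        assert table.rows == {"lncRNA": (1, 1), "protein_coding": (1, 1)}
        assert table.percentage("lncRNA") == 100.0

    def test_crosstab_partial(self):
        ref = make_annotation(
            make_transcript("x1", [(0, 10), (20, 30)], gene_id="g1", biotype="X"),
            make_transcript("x2", [(100, 110), (120, 130)], gene_id="g2", biotype="X"),
        )
        other = make_annotation(make_transcript("o", [(0, 10), (20, 30)], gene_id="h"))
        table = biotype_crosstab(ref, other)
        assert table.rows == {"X": (2, 1)}
        assert table.percentage("X") == 50.0

    def test_stratify_by_biotype(self, ref):
        asm = make_annotation(
            make_transcript("a1", REF_EXONS),
            make_transcript("a2", [(1000, 1100), (1200, 1300)]),
            make_transcript("a3", [(100, 200), (300, 600)]),
        )
        assert stratify_matches_by_biotype(asm, ref) == {"lncRNA": 1, "protein_coding": 1}
        assert stratify_matches_by_biotype(make_annotation(make_transcript("a", [(9000, 9100), (9200, 9300)])), ref) == {}

    def test_exclusive_matches(self, ref):
        ref_b = make_annotation(make_transcript("B1", REF_EXONS, gene_id="g"))
        asm = make_annotation(
            make_transcript("a1", REF_EXONS),                    # in both refs
            make_transcript("a2", [(1000, 1100), (1200, 1300)]),  # only in ref_a
        )
        assert exclusive_matches(asm, ref, ref_b) == {"lncRNA": 1}
        assert exclusive_matches(asm, ref, ref) == {}


def _empty():
    from txcompare import AnnotationSet

    return AnnotationSet()
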