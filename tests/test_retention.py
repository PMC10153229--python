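"""Intron-retention detection: criteria geometry, ratio gate, filtering."""

import pytest

from txcompare import (
    AbundanceRequiredError,
    IRParams,
    brute_force_ir,
    candidate_references,
    check_criterion1,
    check_criterion2,
    check_criterion3,
    detect_ir,
    flagged_transcripts,
    plant_ir,
    random_annotation,
    split_assembly,
)
from txcompare.fixtures import FixtureParams
from txcompare.retention import CallConsistencyError

from conftest import make_annotation, make_transcript


REF = [(100, 200), (300, 400), (500, 600), (700, 800)]  # introns: (200,300),(400,500),(600,700)


def ref_transcript(abundance=10.0):
    return make_transcript("r", REF, abundance=abundance)


class TestRatioGate:
    def test_threshold_is_strict(self):
        t = make_transcript("t", [(100, 800)], abundance=10.0)
        at = make_transcript("r", REF, abundance=5.0)
        above = make_transcript("r", REF, abundance=5.1)
        assert candidate_references(t, make_annotation(t, at)) == []
        assert [r.transcript_id for r in candidate_references(t, make_annotation(t, above))] == ["r"]

    def test_other_chromosome_and_strand_excluded(self):
        t = make_transcript("t", [(100, 800)], abundance=1.0)
        other_chrom = make_transcript("c", REF, chrom="chr2", abundance=10.0)
        other_strand = make_transcript("s", REF, strand="-", abundance=10.0)
        ann = make_annotation(t, other_chrom, other_strand)
        assert candidate_references(t, ann) == []
        relaxed = IRParams(require_same_strand=False)
        assert [r.transcript_id for r in candidate_references(t, ann, relaxed)] == ["s"]

    def test_missing_abundance_raises_unless_ignored(self):
        t = make_transcript("t", [(100, 800)])
        r = make_transcript("r", REF, abundance=10.0)
        ann = make_annotation(t, r)
        with pytest.raises(AbundanceRequiredError):
            candidate_references(t, ann)
        ignored = IRParams(ignore_abundance=True)
        assert [x.transcript_id for x in candidate_references(t, ann, ignored)] == ["r"]


class TestCriteria:
    def test_criterion1_first_exon_crosses_acceptor(self):
        r = ref_transcript()
        hit = make_transcript("t", [(450, 600), (700, 800)])
        assert check_criterion1(hit, r)
        inside_intron = make_transcript("t", [(420, 480), (700, 800)])
        assert not check_criterion1(inside_intron, r)  # never reaches the exon
        same_chain = make_transcript("t", REF)
        assert not check_criterion1(same_chain, r)

    def test_criterion2_last_exon_crosses_donor(self):
        r = ref_transcript()
        hit = make_transcript("t", [(300, 400), (500, 650)])
        assert check_criterion2(hit, r)
        stops_at_donor = make_transcript("t", [(300, 400), (500, 600)])
        assert not check_criterion2(stops_at_donor, r)  # half-open: no intron base
        left_of_all = make_transcript("t", [(10, 90)])
        assert not check_criterion2(left_of_all, r)

    def test_criterion3_full_intron_coverage(self):
        r = ref_transcript()
        covering = make_transcript("t", [(100, 200), (390, 510)])
        assert check_criterion3(covering, r)
        exact = make_transcript("t", [(400, 500)])
        assert check_criterion3(exact, r)  # equality counts as covered
        one_short = make_transcript("t", [(400, 499)])
        assert not check_criterion3(one_short, r)


class TestDetect:
    def test_toy_assembly_flags(self, ir_assembly):
        calls = detect_ir(ir_assembly)
        per_t = {}
        for c in calls:
            per_t.setdefault(c.t_id, set()).add(c.criterion)
        assert per_t == {"t2": {1}, "t3": {2}, "t4": {3}}
        for c in calls:
            assert c.ratio > 0.5

    def test_single_transcript_no_calls(self):
        ann = make_annotation(make_transcript("only", REF, abundance=1.0))
        assert detect_ir(ann) == []

    def test_huge_threshold_blocks_everything(self, ir_assembly):
        assert detect_ir(ir_assembly, IRParams(ratio_threshold=10)) == []

    def test_shared_chain_assembly_is_clean(self):
        # all transcripts share one chain: exons never overlap introns
        ts = [
            make_transcript(f"t{i}", [(100 - 10 * i, 200), (300, 400), (500, 600 + 10 * i)],
                            abundance=float(i + 1))
            for i in range(4)
        ]
        assert detect_ir(make_annotation(*ts)) == []

    def test_zero_abundance_query_skipped(self, ir_assembly):
        dead = make_transcript("dead", [(450, 600), (700, 800)], abundance=0.0)
        ann = make_annotation(*ir_assembly.transcripts.values(), dead)
        assert "dead" not in flagged_transcripts(detect_ir(ann))

    @pytest.mark.parametrize("seed", range(50))
    def test_threshold_monotonicity(self, seed):
        params = FixtureParams(seed=seed, n_genes=3)
        ann, _ = plant_ir(random_annotation(params), params)
        prev = None
        for thr in (0.0, 0.25, 0.5, 1.0, 2.0):
            flagged = flagged_transcripts(detect_ir(ann, IRParams(ratio_threshold=thr)))
            if prev is not None:
                assert flagged <= prev
            prev = flagged

    @pytest.mark.parametrize("seed", range(50))
    def test_abundance_scale_invariance(self, seed):
        params = FixtureParams(seed=seed, n_genes=3)
        ann, _ = plant_ir(random_annotation(params), params)
        scaled = make_annotation(*(t.copy() for t in ann.transcripts.values()))
        for t in scaled.transcripts.values():
            t.abundance *= 7.3
        base = [(c.t_id, c.r_id, c.criterion) for c in detect_ir(ann)]
        after = [(c.t_id, c.r_id, c.criterion) for c in detect_ir(scaled)]
        assert base == after


class TestSplit:
    def test_toy_partition(self, ir_assembly):
        calls = detect_ir(ir_assembly)
        kept, removed = split_assembly(ir_assembly, calls)
        assert sorted(kept.transcripts) == ["t1"]
        assert sorted(removed.transcripts) == ["t2", "t3", "t4"]
        assert set(kept.transcripts) | set(removed.transcripts) == set(ir_assembly.transcripts)
        assert not set(kept.transcripts) & set(removed.transcripts)
        assert kept.transcripts["t1"].abundance == 10.0

    def test_zero_calls_keeps_everything(self, small_random):
        kept, removed = split_assembly(small_random, [])
        assert sorted(kept.transcripts) == sorted(small_random.transcripts)
        assert removed.num_transcripts == 0

    def test_unknown_transcript_in_calls(self, ir_assembly):
        from txcompare import IRCall

        with pytest.raises(CallConsistencyError):
            split_assembly(ir_assembly, [IRCall("ghost", "t1", 1, 2.0)])


@pytest.mark.parametrize("seed", range(100))
def test_detect_matches_brute_force_oracle(seed):
    params = FixtureParams(seed=seed, n_genes=4)
    ann, _ = plant_ir(random_annotation(params), params)
    assert detect_ir(ann) == brute_force_ir(ann)
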