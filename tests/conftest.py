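import pytest

from txcompare import (
    AnnotationSet,
    GenomeInterval,
    TranscriptModel,
    random_annotation,
    toy_annotation_pair,
    toy_ir_assembly,
)
from txcompare.fixtures import FixtureParams


def make_transcript(tid, exons, gene_id="G1", chrom="chr1", strand="+",
                    abundance=None, biotype=None):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=[GenomeInterval(chrom, s, e) for s, e in exons],
        abundance=abundance,
        biotype=biotype,
    )


def make_annotation(*transcripts):
    return AnnotationSet.from_transcripts(transcripts)


@pytest.fixture
def toy_pair():
    return toy_annotation_pair()


@pytest.fixture
def ir_assembly():
    return toy_ir_assembly()


@pytest.fixture
def small_random():
    return random_annotation(FixtureParams(seed=42, n_genes=5))
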