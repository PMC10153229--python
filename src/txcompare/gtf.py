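"""GTF reading and writing across annotation and assembler dialects.

Handles the attribute-naming quirks of Ensembl, RefSeq, CHM13, StringTie
and Scallop GTFs through a small dialect configuration: which feature
types carry exon structure, which attribute keys hold the transcript and
gene ids, and the precedence order for abundance (``TPM``, ``FPKM``,
``cov``) and biotype (``transcript_biotype``, ...) keys.

Coordinates are converted between GTF's 1-based closed convention and
the package's 0-based half-open convention exactly once, here.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import re
from typing import Optional

from .model import (
    AnnotationSet,
    GenomeInterval,
    StructuralValidationError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

# `key "value";` or `key value;` (RefSeq-ish unquoted numerics); tolerates
# a missing trailing semicolon on the last pair.
_ATTR_RE = re.compile(r'\s*([\w.\-:]+)\s+(?:"([^"]*)"|([^;\s]+))\s*(?:;|$)')


@dataclasses.dataclass
class GtfDialect:
    """Attribute-key configuration for one GTF flavor.

    ``abundance_keys`` are tried in order; the first present wins. The
    defaults (TPM before FPKM before cov) prefer normalised abundance
    units over raw read coverage.
    """

    feature_types_kept: frozenset = frozenset({"exon"})
    transcript_id_key: str = "transcript_id"
    gene_id_key: str = "gene_id"
    biotype_keys: tuple = ("transcript_biotype", "transcript_type", "gbkey")
    abundance_keys: tuple = ("TPM", "FPKM", "cov")

    def __post_init__(self) -> None:
        if not self.transcript_id_key or not self.gene_id_key:
            raise ValueError("transcript/gene id keys must be non-empty")


DEFAULT_DIALECT = GtfDialect()


class GtfReadError(ValueError):
    """Raised for unreadable files or files with no parseable structure."""


def parse_attributes(field: str) -> dict:
    """Parse a GTF column-9 attribute string into a key->value map.

    Best-effort: tolerates unquoted values and a missing trailing
    semicolon; duplicate keys keep the first occurrence.
    """
    out: dict = {}
    for m in _ATTR_RE.finditer(field):
        key = m.group(1)
        value = m.group(2) if m.group(2) is not None else m.group(3)
        if key not in out:
            out[key] = value
    return out


def _first_key(attrs: dict, keys) -> Optional[str]:
    for k in keys:
        if k in attrs:
            return attrs[k]
    return None


def read_gtf(
    path,
    dialect: GtfDialect = DEFAULT_DIALECT,
    merge_adjacent: bool = False,
) -> AnnotationSet:
    """Read a GTF file into an :class:`AnnotationSet`.

    Transcripts are assembled from ``exon`` features grouped by
    transcript id; ``transcript`` features are scanned for transcript-
    level attributes (abundance, biotype) with exon-level attributes as
    fallback. Malformed lines, and transcripts whose exons span multiple
    chromosomes or strands, are logged and dropped rather than raised.

    ``merge_adjacent`` repairs zero-gap consecutive exons by merging
    them; without it such transcripts are rejected (zero gaps indicate
    an upstream bug, not a real intron).
    """
    if not os.path.exists(path):
        raise GtfReadError(f"GTF file not found: {path}")

    exons: dict = {}  # tid -> list[(chrom, strand, start0, end0)]
    tx_attrs: dict = {}  # tid -> transcript-feature attributes
    exon_attrs: dict = {}  # tid -> first exon-feature attributes
    n_malformed = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                n_malformed += 1
                logger.warning("%s:%d: fewer than 9 columns, skipped", path, lineno)
                continue
            chrom, _source, feature, start, end, _score, strand, _frame, attr_field = cols[:9]
            if feature not in dialect.feature_types_kept and feature != "transcript":
                continue
            attrs = parse_attributes(attr_field)
            tid = attrs.get(dialect.transcript_id_key)
            if tid is None:
                n_malformed += 1
                logger.warning(
                    "%s:%d: %s feature lacks %s, skipped",
                    path, lineno, feature, dialect.transcript_id_key,
                )
                continue
            if feature == "transcript":
                tx_attrs.setdefault(tid, attrs)
                continue
            try:
                start0, end0 = int(start) - 1, int(end)  # 1-based closed -> 0-based half-open
            except ValueError:
                n_malformed += 1
                logger.warning("%s:%d: non-integer coordinates, skipped", path, lineno)
                continue
            exons.setdefault(tid, []).append((chrom, strand, start0, end0))
            exon_attrs.setdefault(tid, attrs)

    transcripts = []
    for tid in sorted(exons):
        rows = exons[tid]
        chroms = {r[0] for r in rows}
        strands = {r[1] for r in rows}
        if len(chroms) > 1 or len(strands) > 1:
            logger.warning(
                "transcript %s spans multiple chromosomes/strands, rejected", tid
            )
            continue
        chrom, strand = rows[0][0], rows[0][1]
        ivals = sorted((s, e) for _, _, s, e in rows)
        if merge_adjacent:
            merged: list = []
            for s, e in ivals:
                if merged and s == merged[-1][1]:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            ivals = merged
        attrs = tx_attrs.get(tid, exon_attrs.get(tid, {}))
        abundance = _parse_abundance(tid, tx_attrs.get(tid), exon_attrs.get(tid), dialect)
        biotype = _first_key(attrs, dialect.biotype_keys)
        gene_id = attrs.get(dialect.gene_id_key) or tid
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand if strand in ("+", "-") else ".",
                    exons=[GenomeInterval(chrom, s, e) for s, e in ivals],
                    abundance=abundance,
                    biotype=biotype,
                    attributes=attrs,
                )
            )
        except StructuralValidationError as exc:
            logger.warning("transcript %s rejected: %s", tid, exc)

    if n_malformed:
        logger.info("%s: %d malformed lines skipped", path, n_malformed)
    return AnnotationSet.from_transcripts(transcripts)


def _parse_abundance(tid, tx_attrs, exon_attrs, dialect) -> Optional[float]:
    for attrs in (tx_attrs, exon_attrs):
        if not attrs:
            continue
        raw = _first_key(attrs, dialect.abundance_keys)
        if raw is not None:
            try:
                return float(raw)
            except ValueError:
                logger.warning("transcript %s: unparseable abundance %r", tid, raw)
                return None
    return None


def write_gtf(annotation: AnnotationSet, path, source: str = "txcompare") -> None:
    """Write ``annotation`` as GTF (transcript + exon features).

    Coordinates convert back to 1-based closed. Original attributes are
    preserved; an abundance or biotype held only on the model is emitted
    under ``TPM`` / ``transcript_biotype`` so that a read/write round
    trip reproduces coordinates, ids, abundances and biotypes.
    """
    lines = []
    for t in sorted(
        annotation.transcripts.values(),
        key=lambda t: (t.chrom, t.start, t.transcript_id),
    ):
        attrs = dict(t.attributes)
        attrs.pop("gene_id", None)
        attrs.pop("transcript_id", None)
        if t.abundance is not None and not any(
            k in attrs for k in DEFAULT_DIALECT.abundance_keys
        ):
            attrs["TPM"] = repr(t.abundance)
        if t.biotype is not None and not any(
            k in attrs for k in DEFAULT_DIALECT.biotype_keys
        ):
            attrs["transcript_biotype"] = t.biotype
        attr_str = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        for k, v in attrs.items():
            attr_str += f' {k} "{v}";'
        base = (t.chrom, source)
        lines.append(
            "\t".join(
                map(str, (*base, "transcript", t.start + 1, t.end, ".", t.strand, ".", attr_str))
            )
        )
        for e in t.exons:
            lines.append(
                "\t".join(
                    map(str, (*base, "exon", e.start + 1, e.end, ".", t.strand, ".", attr_str))
                )
            )
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
    os.replace(tmp, path)
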