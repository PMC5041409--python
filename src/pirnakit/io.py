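"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open throughout the package; GFF3
(1-based closed) and BED (already half-open) are converted at this boundary
and nowhere else.  All sequences are normalised to the upper-case DNA
alphabet on input (U -> T), so mapping and logo arithmetic see one alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from gffutils.feature import feature_from_line

logger = logging.getLogger("pirnakit")

REPEAT_CLASSES = ("LINE", "LTR", "SINE", "DNA", "Helitron", "Satellite")
NCRNA_KINDS = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")
GENE_SUBFEATURES = ("CDS", "five_prime_UTR", "three_prime_UTR", "intron")
KNOWN_KINDS = (
    ("gene", "exon") + GENE_SUBFEATURES + NCRNA_KINDS + ("repeat",)
)


@dataclass(frozen=True)
class GenomeSequence:
    """A reference contig (upper-case DNA over {A,C,G,T,N})."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    """One genomic feature in internal 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    feature_kind: str
    repeat_class: Optional[str] = None
    repeat_family: Optional[str] = None
    parent_id: Optional[str] = None
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.feature_kind}"
            )
        if (self.feature_kind == "repeat") != (self.repeat_class is not None):
            raise ValueError("repeat_class must be present iff feature_kind is repeat")
        if self.repeat_class is not None and self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class ParseError(ValueError):
    """Malformed record in an input file; the message names the location."""


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_sequences(path: str | Path, format: str = None):
    """Read a FASTA or FASTQ file into (read_id, sequence[, quality]) tuples.

    Sequences are upper-cased with U converted to T.  Records whose quality
    string length disagrees with the sequence length raise :class:`ParseError`.
    """
    path = Path(path)
    if format is None:
        format = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format {format!r}")
    out = []
    try:
        for rec in SeqIO.parse(str(path), format):
            seq = _normalise(str(rec.seq))
            if format == "fastq":
                quals = rec.letter_annotations.get("phred_quality", [])
                out.append((rec.id, seq, quals))
            else:
                out.append((rec.id, seq))
    except ValueError as exc:  # Biopython reports the offending record
        raise ParseError(f"{path}: {exc}") from exc
    if not out:
        logger.warning("no records parsed from %s", path)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs with uniform Sanger quality 'I'."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_genome(path: str | Path) -> list[GenomeSequence]:
    genome = [GenomeSequence(rid, seq) for rid, seq in read_sequences(path, "fasta")]
    ids = [g.contig_id for g in genome]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate contig ids")
    return genome


def write_genome(genome: Iterable[GenomeSequence], path: str | Path) -> None:
    write_fasta(((g.contig_id, g.sequence) for g in genome), path)


def _parse_repeat_name(name: str) -> tuple[Optional[str], Optional[str]]:
    """Split the 'CLASS/Family' repeat-name dialect (family optional)."""
    cls, _, family = name.partition("/")
    if cls in REPEAT_CLASSES:
        return cls, family or None
    return None, None


def _record_from_gff_line(line: str, lineno: int, path) -> Optional[AnnotationRecord]:
    feat = feature_from_line(line)
    kind = feat.featuretype
    repeat_class = repeat_family = None
    if kind in ("repeat", "repeat_region", "dispersed_repeat"):
        kind = "repeat"
        name = feat.attributes.get("Name", [""])[0] or feat.attributes.get("ID", [""])[0]
        repeat_class, repeat_family = _parse_repeat_name(name)
        if repeat_class is None:
            logger.warning("%s:%d: repeat without CLASS/Family name, skipped", path, lineno)
            return None
    elif kind not in KNOWN_KINDS:
        logger.warning("%s:%d: unknown feature kind %r, skipped", path, lineno, kind)
        return None
    start = feat.start - 1  # GFF3 is 1-based closed
    end = feat.end
    if start >= end or start < 0:
        logger.warning("%s:%d: rejected degenerate interval", path, lineno)
        return None
    parent = feat.attributes.get("Parent", [None])[0]
    rec_id = feat.attributes.get("ID", [None])[0]
    return AnnotationRecord(
        contig_id=feat.seqid,
        start=start,
        end=end,
        strand=feat.strand if feat.strand in "+-" else ".",
        feature_kind=kind,
        repeat_class=repeat_class,
        repeat_family=repeat_family,
        parent_id=parent,
        record_id=rec_id,
    )


def _record_from_bed_line(line: str, lineno: int, path) -> Optional[AnnotationRecord]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: BED line with <3 fields")
    contig, start, end = fields[0], int(fields[1]), int(fields[2])
    if start >= end:
        logger.warning("%s:%d: rejected degenerate interval", path, lineno)
        return None
    name = fields[3] if len(fields) > 3 else ""
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
    repeat_class, repeat_family = _parse_repeat_name(name)
    if repeat_class is not None:
        kind = "repeat"
    elif name in KNOWN_KINDS:
        kind = name
    else:
        logger.warning("%s:%d: unknown feature kind %r, skipped", path, lineno, name)
        return None
    return AnnotationRecord(
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        feature_kind=kind,
        repeat_class=repeat_class,
        repeat_family=repeat_family,
        record_id=name or None,
    )


def synthesize_introns(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Fill intron records as gaps between consecutive exons of one parent.

    Explicit intron records suppress synthesis for their parent.
    """
    have_introns = {r.parent_id for r in records if r.feature_kind == "intron"}
    by_parent: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        if rec.feature_kind == "exon" and rec.parent_id:
            by_parent.setdefault(rec.parent_id, []).append(rec)
    introns = []
    for parent, exons in by_parent.items():
        if parent in have_introns:
            continue
        exons = sorted(exons, key=lambda r: r.start)
        for left, right in zip(exons, exons[1:]):
            if right.start > left.end:
                introns.append(
                    AnnotationRecord(
                        contig_id=left.contig_id,
                        start=left.end,
                        end=right.start,
                        strand=left.strand,
                        feature_kind="intron",
                        parent_id=parent,
                    )
                )
    return records + introns


def read_annotations(path: str | Path, format: str = None) -> list[AnnotationRecord]:
    """Read GFF3 or BED annotations into internal half-open records.

    Introns absent from the file are synthesised from each gene's exon chain.
    """
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix.lower() == ".bed" else "gff3"
    if format not in ("gff3", "bed"):
        raise ValueError(f"unsupported annotation format {format!r}")
    parse = _record_from_gff_line if format == "gff3" else _record_from_bed_line
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            try:
                rec = parse(line, lineno, path)
            except ParseError:
                raise
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if rec is not None:
                records.append(rec)
    return synthesize_introns(records)


def write_gff3(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = []
            if rec.record_id:
                attrs.append(f"ID={rec.record_id}")
            if rec.feature_kind == "repeat":
                attrs.append(f"Name={rec.repeat_class}/{rec.repeat_family or ''}".rstrip("/"))
            if rec.parent_id:
                attrs.append(f"Parent={rec.parent_id}")
            fh.write(
                "\t".join(
                    [
                        rec.contig_id,
                        "pirnakit",
                        rec.feature_kind,
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


def write_bed(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.feature_kind == "repeat":
                name = f"{rec.repeat_class}/{rec.repeat_family or ''}".rstrip("/")
            else:
                name = rec.record_id or rec.feature_kind
            fh.write(
                f"{rec.contig_id}\t{rec.start}\t{rec.end}\t{name}\t0\t{rec.strand}\n"
            )
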