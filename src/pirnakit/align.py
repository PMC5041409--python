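"""Exact placement of unique tags on the genome.

Tags are placed by exact string match on both strands, reporting every
occurrence; a tag with one placement is `unique`, several `multi`, none
`unmapped`.  Minus-strand occurrences are reported in plus-strand
coordinates with strand '-'; the 5' end of a minus-strand placement is its
rightmost base (end - 1).  Placements can also be ingested from SAM, which
lets a third-party mapper stand in for the internal one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

from .io import GenomeSequence
from .preprocess import UniqueTag

logger = logging.getLogger("pirnakit")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: placement = (contig_id, start, end, strand) in 0-based half-open coords
Placement = tuple[str, int, int, str]


@dataclass
class MappedTag:
    """A tag's genomic placements and its unique/multi/unmapped status."""

    tag: UniqueTag
    placements: list[Placement] = field(default_factory=list)

    @property
    def n_hits(self) -> int:
        return len(self.placements)

    @property
    def mapping_class(self) -> str:
        if self.n_hits == 0:
            return "unmapped"
        return "unique" if self.n_hits == 1 else "multi"

    @property
    def five_prime_positions(self) -> list[tuple[str, int, str]]:
        """5' coordinate per placement: start on '+', end - 1 on '-'."""
        return [
            (contig, start if strand == "+" else end - 1, strand)
            for contig, start, end, strand in self.placements
        ]


class GenomeIndex:
    """Seed-and-verify exact substring index over both strands.

    Every k-mer (k = seed_length) of the plus strand is hashed to its start
    positions; a query anchors on its first k bases and is verified by
    direct string comparison, so matches are exact by construction.
    Queries shorter than the seed fall back to a direct scan.
    """

    def __init__(self, genome: Sequence[GenomeSequence], seed_length: int = 12):
        if not genome:
            raise ValueError("genome must be non-empty")
        self.seed_length = seed_length
        self.contigs = {g.contig_id: g.sequence for g in genome}
        self.order = [g.contig_id for g in genome]
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for cid in self.order:
            seq = self.contigs[cid]
            for i in range(len(seq) - seed_length + 1):
                kmer = seq[i : i + seed_length]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((cid, i))

    def _occurrences(self, pattern: str) -> list[tuple[str, int]]:
        k = self.seed_length
        if len(pattern) < k:
            hits = []
            for cid in self.order:
                seq = self.contigs[cid]
                i = seq.find(pattern)
                while i >= 0:
                    hits.append((cid, i))
                    i = seq.find(pattern, i + 1)
            return hits
        out = []
        for cid, i in self._seeds.get(pattern[: k], ()):
            if self.contigs[cid].startswith(pattern, i):
                out.append((cid, i))
        return out

    def query(self, pattern: str) -> list[Placement]:
        """All exact occurrences of ``pattern`` on either strand."""
        if not pattern or "N" in pattern:
            return []
        L = len(pattern)
        placements = [
            (cid, i, i + L, "+") for cid, i in self._occurrences(pattern)
        ] + [
            (cid, i, i + L, "-") for cid, i in self._occurrences(revcomp(pattern))
        ]
        placements.sort(key=lambda p: (p[0], p[1], p[3]))
        return placements


def build_index(genome: Sequence[GenomeSequence], seed_length: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, seed_length)


def map_tags(tags: Iterable[UniqueTag], index: GenomeIndex) -> list[MappedTag]:
    """Place every tag; deterministic placement order (contig, start, strand)."""
    return [MappedTag(tag, index.query(tag.sequence)) for tag in tags]


def split_by_class(mapped: Iterable[MappedTag]):
    """Partition into (unique, multi, unmapped) lists."""
    unique, multi, unmapped = [], [], []
    for mt in mapped:
        {"unique": unique, "multi": multi, "unmapped": unmapped}[mt.mapping_class].append(mt)
    return unique, multi, unmapped


def ingest_sam(path, counts_by_read: Optional[dict] = None) -> list[MappedTag]:
    """Build mapped tags from a SAM file of ungapped, mismatch-free records.

    Only records whose CIGAR is a single full-length match and whose NM tag
    is 0 (or absent) are accepted; soft-clips, indels and mismatched records
    are skipped and tallied.  Flag 16 yields a '-' placement whose tag
    sequence is the reverse complement of the stored SEQ.  Records are
    grouped into tags by original read sequence; per-tag counts default to
    the number of distinct read names observed (``counts_by_read`` maps
    read name -> (library, count) to carry real counts).
    """
    n_skipped = 0
    table: dict[str, MappedTag] = {}
    names_per_tag: dict[str, set] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                n_skipped += 1
                continue
            if len(rec.cigartuples) != 1 or rec.cigartuples[0][0] != 0:
                n_skipped += 1
                continue
            if rec.cigartuples[0][1] != len(rec.query_sequence):
                n_skipped += 1
                continue
            if rec.has_tag("NM") and rec.get_tag("NM") != 0:
                n_skipped += 1
                continue
            seq = rec.query_sequence.upper()
            strand = "-" if rec.is_reverse else "+"
            tag_seq = revcomp(seq) if strand == "-" else seq
            mt = table.get(tag_seq)
            if mt is None:
                mt = table[tag_seq] = MappedTag(UniqueTag(tag_seq))
                names_per_tag[tag_seq] = set()
            names_per_tag[tag_seq].add(rec.query_name)
            placement = (
                rec.reference_name,
                rec.reference_start,
                rec.reference_start + len(seq),
                strand,
            )
            if placement not in mt.placements:
                mt.placements.append(placement)
    if n_skipped:
        logger.info("ingest_sam: skipped %d non-exact records", n_skipped)
    for tag_seq, mt in table.items():
        mt.placements.sort(key=lambda p: (p[0], p[1], p[3]))
        if counts_by_read:
            for name in names_per_tag[tag_seq]:
                if name in counts_by_read:
                    lib, n = counts_by_read[name]
                    mt.tag.counts[lib] += n
        else:
            mt.tag.counts["all"] = len(names_per_tag[tag_seq])
    return sorted(table.values(), key=lambda m: m.tag.sequence)
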