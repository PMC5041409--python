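"""Raw reads -> unique-tag table.

The cleaning chain is: 3'-adapter trim, drop reads containing N, drop reads
shorter than the keep threshold, select piRNA-sized reads (24-30 nt),
remove homopolymer artifacts (a run of >= 8 identical bases anywhere), and
collapse identical sequences into unique tags with per-library counts.
ncRNA-derived tags are excluded after mapping, by genomic overlap of any
placement with an rRNA/tRNA/snRNA/snoRNA/miRNA interval.

Gene-exon overlapping tags are deliberately KEPT: they form the gene-derived
piRNA class analysed downstream, while structural ncRNAs are contamination.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io import AnnotationRecord, NCRNA_KINDS

logger = logging.getLogger("pirnakit")


@dataclass
class UniqueTag:
    """A distinct small-RNA sequence with per-library read counts."""

    sequence: str
    counts: Counter = field(default_factory=Counter)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CleaningStats:
    """Per-library accounting of the cleaning chain (no silent drops)."""

    n_input: int = 0
    n_adapter_dropped: int = 0  # empty or below keep-min after trimming
    n_with_n: int = 0
    n_length_dropped: int = 0
    n_homopolymer_dropped: int = 0
    n_kept: int = 0
    length_spectrum: Counter = field(default_factory=Counter)

    def conserved(self) -> bool:
        return self.n_input == (
            self.n_adapter_dropped
            + self.n_with_n
            + self.n_length_dropped
            + self.n_homopolymer_dropped
            + self.n_kept
        )


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str:
    """Remove the longest read suffix that exactly matches an adapter prefix.

    The full adapter occurring anywhere in the read (sequencing past the
    3' ligation junction) removes it and everything after; otherwise the
    longest read suffix equal to an adapter prefix of length >= min_overlap
    is removed.  A read with no match is returned unchanged; an empty return
    value means the whole read was adapter.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    idx = read.find(adapter)
    if idx >= 0:
        return read[:idx]
    max_k = min(len(read), len(adapter) - 1)
    for k in range(max_k, min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[: len(read) - k]
    return read


def has_homopolymer(seq: str, min_run: int) -> bool:
    """True when ``seq`` contains >= min_run identical consecutive bases."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= min_run:
            return True
    return False


def select_lengths(reads: Iterable[str], lo: int, hi: int) -> list[str]:
    """Keep reads with lo <= length <= hi (both boundaries inclusive)."""
    if lo > hi:
        raise ValueError("length selection requires lo <= hi")
    return [r for r in reads if lo <= len(r) <= hi]


def filter_homopolymers(reads: Iterable[str], min_run: int = 8) -> list[str]:
    """Drop reads containing a homopolymer run of >= min_run anywhere."""
    return [r for r in reads if not has_homopolymer(r, min_run)]


def clean_reads(
    reads: Iterable[str],
    adapter: str,
    *,
    adapter_min_overlap: int = 6,
    keep_min: int = 18,
    length_lo: int = 24,
    length_hi: int = 30,
    homopolymer_min_run: int = 8,
) -> tuple[list[str], CleaningStats]:
    """Run the full cleaning chain on one library's raw reads.

    Returns the kept piRNA-sized reads and a conservation-checked tally.
    The length spectrum records all reads of >= keep_min nt after trimming,
    i.e. the population the per-library size distribution describes.
    """
    stats = CleaningStats()
    kept = []
    for read in reads:
        stats.n_input += 1
        insert = trim_adapter(read, adapter, adapter_min_overlap)
        if len(insert) < keep_min:
            stats.n_adapter_dropped += 1
            continue
        stats.length_spectrum[len(insert)] += 1
        if "N" in insert:
            stats.n_with_n += 1
            continue
        if not length_lo <= len(insert) <= length_hi:
            stats.n_length_dropped += 1
            continue
        if has_homopolymer(insert, homopolymer_min_run):
            stats.n_homopolymer_dropped += 1
            continue
        stats.n_kept += 1
        kept.append(insert)
    return kept, stats


def collapse_tags(reads_per_library: Mapping[str, Sequence[str]]) -> list[UniqueTag]:
    """Collapse cleaned reads into unique tags with per-library counts.

    One tag per distinct sequence across all libraries; the sum of total
    counts equals the number of input reads.  Output is sorted by
    descending total count, then sequence, so downstream reports are
    deterministic.
    """
    table: dict[str, UniqueTag] = {}
    for lib, reads in reads_per_library.items():
        for seq in reads:
            tag = table.get(seq)
            if tag is None:
                tag = table[seq] = UniqueTag(seq)
            tag.counts[lib] += 1
    return sorted(table.values(), key=lambda t: (-t.total_count, t.sequence))


def build_ncrna_trees(annotations: Iterable[AnnotationRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in annotations:
        if rec.feature_kind in NCRNA_KINDS:
            trees.setdefault(rec.contig_id, IntervalTree()).addi(
                rec.start, rec.end, rec.feature_kind
            )
    return trees


def exclude_ncRNA(mapped_tags, annotations: Iterable[AnnotationRecord]):
    """Partition mapped tags into piRNA-like and ncRNA-overlapping.

    A tag is excluded when ANY of its genomic placements overlaps an
    rRNA/tRNA/snRNA/snoRNA/miRNA interval by >= 1 bp; the overlapped kind is
    recorded as the exclusion reason.  Returns (kept, [(tag, reason), ...]).
    """
    trees = build_ncrna_trees(annotations)
    if not trees:
        logger.warning("no ncRNA annotation present; no tags excluded")
        return list(mapped_tags), []
    kept, excluded = [], []
    for mt in mapped_tags:
        reason = None
        for contig, start, end, _strand in mt.placements:
            tree = trees.get(contig)
            if tree is None:
                continue
            hits = tree.overlap(start, end)
            if hits:
                reason = sorted(iv.data for iv in hits)[0]
                break
        if reason is None:
            kept.append(mt)
        else:
            excluded.append((mt, reason))
    return kept, excluded
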