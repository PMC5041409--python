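"""piRNA cluster calling by dense-window scanning.

A cluster is a genomic locus where many distinct piRNA sequences
concentrate.  The caller marks every 5-kb window holding >= 10 distinct
piRNA sequences, merges marked windows less than 20 kb apart (edge to
edge), and trims each merged locus to the outermost mapped piRNA
coordinates inside it.  Cluster calling uses all exact placements of
abundantly supported tags (>= 200 reads across libraries, applied per tag
before calling and again as a >= 200-read support filter per cluster), so
multi-mapping piRNAs contribute at every placement.

The scan is event-driven and exactly equivalent to evaluating every
possible window start position: the distinct-sequence count of the window
starting at s changes only at placement boundaries, so qualifying start
positions are found by a sweep over those breakpoints rather than by
stepping a fixed stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import MappedTag
from .io import AnnotationRecord, GenomeSequence

logger = logging.getLogger("pirnakit")

#: stream entry: (contig, start, end, strand, tag_sequence)
StreamEntry = tuple[str, int, int, str, str]


@dataclass
class PiRNACluster:
    contig: str
    start: int
    end: int
    n_distinct_piRNAs: int
    support_reads_total: int
    tag_sequences: list[str] = field(default_factory=list)
    tpm_per_library: dict[str, float] = field(default_factory=dict)
    strandness: Optional[str] = None
    contains_TE: bool = False
    te_list: list[str] = field(default_factory=list)
    contains_gene: bool = False
    gene_list: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def eligible_reads(
    mapped: Iterable[MappedTag], min_support_reads: int = 200
) -> list[StreamEntry]:
    """Placement stream for cluster calling.

    Tags below the per-tag read-support prefilter are excluded outright;
    every placement of a surviving tag contributes one entry.  The stream
    is sorted by (contig, start).
    """
    stream: list[StreamEntry] = []
    for mt in mapped:
        if mt.tag.total_count < min_support_reads:
            continue
        for contig, start, end, strand in mt.placements:
            stream.append((contig, start, end, strand, mt.tag.sequence))
    stream.sort(key=lambda e: (e[0], e[1], e[2], e[3]))
    return stream


def _qualifying_regions(
    placements: Sequence[tuple[int, int, str]],
    contig_len: int,
    window: int,
    min_sequences: int,
) -> list[tuple[int, int]]:
    """Genomic footprint of all windows holding >= min_sequences sequences.

    Windows are [s, s+window) for every integer s in [0, S] with
    S = max(contig_len - window, 0); a sequence is in a window when any of
    its placements overlaps it by >= 1 bp.  Returns merged [start, end)
    regions covered by qualifying windows.
    """
    S = max(contig_len - window, 0)
    # union of valid window-start intervals per distinct sequence
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for start, end, seq in placements:
        a = max(start - window + 1, 0)
        b = min(end - 1, S)  # inclusive upper bound on s
        if a <= b:
            per_seq.setdefault(seq, []).append((a, b))
    events: list[tuple[int, int]] = []
    for ivs in per_seq.values():
        ivs.sort()
        cur_a, cur_b = ivs[0]
        merged = []
        for a, b in ivs[1:]:
            if a <= cur_b + 1:
                cur_b = max(cur_b, b)
            else:
                merged.append((cur_a, cur_b))
                cur_a, cur_b = a, b
        merged.append((cur_a, cur_b))
        for a, b in merged:
            events.append((a, 1))
            events.append((b + 1, -1))
    if not events:
        return []
    events.sort()
    regions: list[tuple[int, int]] = []
    depth = 0
    open_s: Optional[int] = None
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        if depth >= min_sequences and open_s is None:
            open_s = pos
        elif depth < min_sequences and open_s is not None:
            # window starts in [open_s, pos) qualify -> genomic cover
            regions.append((open_s, pos - 1 + window))
            open_s = None
    if open_s is not None:
        regions.append((open_s, S + window))
    return regions


def call_clusters(
    stream: Sequence[StreamEntry],
    genome: Sequence[GenomeSequence],
    window: int = 5000,
    min_sequences: int = 10,
    merge_gap: int = 20000,
) -> list[PiRNACluster]:
    """Call cluster loci from the eligible placement stream.

    Qualifying-window footprints separated by < merge_gap (edge to edge)
    merge into one locus; each locus is then trimmed to the extreme
    coordinates of the placements overlapping its merged span.  Support
    totals and TPM are attached by :func:`quantify_clusters`.
    """
    contig_lens = {g.contig_id: g.length for g in genome}
    by_contig: dict[str, list] = {}
    for contig, start, end, strand, seq in stream:
        if contig not in contig_lens:
            raise ValueError(f"placement on unknown contig {contig!r}")
        by_contig.setdefault(contig, []).append((start, end, strand, seq))
    clusters: list[PiRNACluster] = []
    for contig in sorted(by_contig):
        entries = by_contig[contig]
        regions = _qualifying_regions(
            [(s, e, q) for s, e, _, q in entries],
            contig_lens[contig],
            window,
            min_sequences,
        )
        if not regions:
            continue
        merged: list[tuple[int, int]] = [regions[0]]
        for a, b in regions[1:]:
            if a - merged[-1][1] < merge_gap:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        for a, b in merged:
            inside = [(s, e, st, q) for s, e, st, q in entries if s < b and e > a]
            seqs = sorted({q for _, _, _, q in inside})
            clusters.append(
                PiRNACluster(
                    contig=contig,
                    start=min(s for s, _, _, _ in inside),
                    end=max(e for _, e, _, _ in inside),
                    n_distinct_piRNAs=len(seqs),
                    support_reads_total=0,
                    tag_sequences=seqs,
                )
            )
    return clusters


def quantify_clusters(
    clusters: list[PiRNACluster],
    counts_by_sequence: Mapping[str, Mapping[str, int]],
    library_totals: Mapping[str, int],
    min_support_reads: int = 200,
) -> list[PiRNACluster]:
    """Attach read support and per-library TPM; drop under-supported loci.

    TPM(cluster, lib) = reads(cluster, lib) x 1e6 / library_totals[lib]; a
    cluster's reads in a library are the summed counts of its distinct
    member sequences.  Clusters whose raw read total over all libraries is
    below ``min_support_reads`` are removed.
    """
    kept = []
    for cl in clusters:
        per_lib: dict[str, int] = {lib: 0 for lib in library_totals}
        for seq in cl.tag_sequences:
            for lib, n in counts_by_sequence.get(seq, {}).items():
                per_lib[lib] = per_lib.get(lib, 0) + n
        cl.support_reads_total = sum(per_lib.values())
        if cl.support_reads_total < min_support_reads:
            continue
        cl.tpm_per_library = {
            lib: (n * 1e6 / library_totals[lib]) if library_totals.get(lib) else float("nan")
            for lib, n in per_lib.items()
        }
        kept.append(cl)
    dropped = len(clusters) - len(kept)
    if dropped:
        logger.info("quantify_clusters: dropped %d under-supported loci", dropped)
    return kept


def type_strandness(cluster: PiRNACluster, stream: Sequence[StreamEntry]) -> str:
    """plus_only / minus_only / divergent_non_overlapping / mixed_overlapping.

    Divergent means both strands occur but their placement spans do not
    overlap; interleaved dual-strand loci are reported as the residual
    mixed_overlapping state rather than forced into a class.
    """
    plus_span = minus_span = None
    for contig, start, end, strand, _seq in stream:
        if contig != cluster.contig or start >= cluster.end or end <= cluster.start:
            continue
        span = plus_span if strand == "+" else minus_span
        span = (start, end) if span is None else (min(span[0], start), max(span[1], end))
        if strand == "+":
            plus_span = span
        else:
            minus_span = span
    if plus_span and not minus_span:
        return "plus_only"
    if minus_span and not plus_span:
        return "minus_only"
    if not plus_span and not minus_span:
        return "plus_only"  # unreachable for called clusters
    if plus_span[1] <= minus_span[0] or minus_span[1] <= plus_span[0]:
        return "divergent_non_overlapping"
    logger.info(
        "cluster %s:%d-%d has overlapping dual-strand placements",
        cluster.contig, cluster.start, cluster.end,
    )
    return "mixed_overlapping"


def cluster_content(
    cluster: PiRNACluster, annotations: Iterable[AnnotationRecord]
) -> None:
    """Flag TEs and coding genes overlapping the cluster (>= 1 bp)."""
    tes, genes = [], []
    for rec in annotations:
        if rec.contig_id != cluster.contig:
            continue
        if rec.start >= cluster.end or rec.end <= cluster.start:
            continue
        if rec.feature_kind == "repeat":
            tes.append(f"{rec.repeat_class}/{rec.repeat_family or ''}".rstrip("/"))
        elif rec.feature_kind == "gene":
            genes.append(rec.record_id or f"gene@{rec.start}")
    cluster.contains_TE = bool(tes)
    cluster.te_list = sorted(tes)
    cluster.contains_gene = bool(genes)
    cluster.gene_list = sorted(genes)


def clusters_frame(clusters: Sequence[PiRNACluster], libraries: Sequence[str]) -> pd.DataFrame:
    rows = []
    for i, cl in enumerate(clusters, start=1):
        row = {
            "cluster_id": f"cluster_{i}",
            "contig": cl.contig,
            "start": cl.start,
            "end": cl.end,
            "length": cl.length,
            "n_distinct_piRNAs": cl.n_distinct_piRNAs,
            "support_reads_total": cl.support_reads_total,
            "strandness": cl.strandness,
            "contains_TE": cl.contains_TE,
            "TE_content": ",".join(cl.te_list),
            "contains_gene": cl.contains_gene,
            "gene_content": ",".join(cl.gene_list),
        }
        for lib in libraries:
            row[f"tpm_{lib}"] = cl.tpm_per_library.get(lib, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_clusters_bed(clusters: Sequence[PiRNACluster], path) -> None:
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters, start=1):
            strand = {"plus_only": "+", "minus_only": "-"}.get(cl.strandness, ".")
            fh.write(
                f"{cl.contig}\t{cl.start}\t{cl.end}\tcluster_{i}\t"
                f"{cl.support_reads_total}\t{strand}\n"
            )
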