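"""Genomic-feature assignment of uniquely mapped piRNA tags.

Each uniquely mapped tag is placed in exactly one of three mutually
exclusive categories -- repeat, gene or intergenic -- with sense/antisense
orientation relative to the overlapped feature.  Precedence when overlaps
conflict is repeat > gene > intergenic (a repeat inside an intron counts as
repeat: TE silencing is the pathway's primary function, so TE origin wins),
and within genes CDS > UTRs > intron; remaining ties break by longest
overlap, then leftmost feature.  Multi-mapping tags are excluded from
composition statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from intervaltree import IntervalTree

from .align import MappedTag
from .io import AnnotationRecord, GENE_SUBFEATURES, REPEAT_CLASSES

logger = logging.getLogger("pirnakit")

_SUBFEATURE_RANK = {"CDS": 0, "five_prime_UTR": 1, "three_prime_UTR": 1, "intron": 2}


@dataclass(frozen=True)
class FeatureAssignment:
    """One tag's category, sub-classification and orientation."""

    tag_sequence: str
    category: str  # repeat | gene | intergenic
    repeat_class: Optional[str] = None
    repeat_family: Optional[str] = None
    gene_subfeature: Optional[str] = None
    orientation: str = "n/a"  # sense | antisense | n/a
    basis_placement: Optional[tuple] = None


class FeatureIndex:
    """Interval trees over repeats, gene subfeatures and gene spans."""

    def __init__(self, annotations: Iterable[AnnotationRecord]):
        self.repeats: dict[str, IntervalTree] = {}
        self.gene_parts: dict[str, IntervalTree] = {}
        self.genes: dict[str, IntervalTree] = {}
        n_rep = 0
        for rec in annotations:
            if rec.feature_kind == "repeat":
                self.repeats.setdefault(rec.contig_id, IntervalTree()).addi(
                    rec.start, rec.end, rec
                )
                n_rep += 1
            elif rec.feature_kind in GENE_SUBFEATURES:
                self.gene_parts.setdefault(rec.contig_id, IntervalTree()).addi(
                    rec.start, rec.end, rec
                )
            elif rec.feature_kind == "gene":
                self.genes.setdefault(rec.contig_id, IntervalTree()).addi(
                    rec.start, rec.end, rec
                )
        if n_rep == 0:
            logger.warning("no repeat annotation present; repeat categories will be empty")


def _best_hit(tree: Optional[IntervalTree], start: int, end: int, rank=None):
    """Deterministic best overlap: precedence rank, longest overlap, leftmost."""
    if tree is None:
        return None
    hits = tree.overlap(start, end)
    if not hits:
        return None

    def key(iv):
        rec = iv.data
        overlap = min(end, iv.end) - max(start, iv.begin)
        return (
            rank(rec) if rank else 0,
            -overlap,
            iv.begin,
            iv.end,
            rec.strand,
        )

    return min(hits, key=key).data


def _orient(tag_strand: str, feature_strand: str) -> str:
    if feature_strand == ".":
        return "n/a"
    return "sense" if tag_strand == feature_strand else "antisense"


def assign_category(mapped_tag: MappedTag, index: FeatureIndex) -> FeatureAssignment:
    """Categorise one uniquely mapped tag via its single placement."""
    if mapped_tag.mapping_class != "unique":
        raise ValueError("assign_category requires a uniquely mapped tag")
    contig, start, end, strand = mapped_tag.placements[0]
    placement = (contig, start, end, strand)
    rep = _best_hit(index.repeats.get(contig), start, end)
    if rep is not None:
        return FeatureAssignment(
            mapped_tag.tag.sequence,
            "repeat",
            repeat_class=rep.repeat_class,
            repeat_family=rep.repeat_family,
            orientation=_orient(strand, rep.strand),
            basis_placement=placement,
        )
    part = _best_hit(
        index.gene_parts.get(contig),
        start,
        end,
        rank=lambda r: _SUBFEATURE_RANK[r.feature_kind],
    )
    if part is not None:
        return FeatureAssignment(
            mapped_tag.tag.sequence,
            "gene",
            gene_subfeature=part.feature_kind,
            orientation=_orient(strand, part.strand),
            basis_placement=placement,
        )
    return FeatureAssignment(
        mapped_tag.tag.sequence, "intergenic", basis_placement=placement
    )


def assign_all(unique_tags: Iterable[MappedTag], index: FeatureIndex):
    return [assign_category(mt, index) for mt in unique_tags]


def _ratio(sense: float, antisense: float) -> float:
    """sense/antisense; inf flags an empty antisense side, nan an empty group."""
    if antisense == 0:
        return float("inf") if sense > 0 else float("nan")
    return sense / antisense


def assignments_frame(
    assignments: Iterable[FeatureAssignment], mapped: Iterable[MappedTag]
) -> pd.DataFrame:
    """Long table: one row per (tag, library) with counts and labels."""
    counts_by_seq = {mt.tag.sequence: mt.tag.counts for mt in mapped}
    rows = []
    for a in assignments:
        for lib, n in sorted(counts_by_seq[a.tag_sequence].items()):
            rows.append(
                {
                    "tag": a.tag_sequence,
                    "library": lib,
                    "count": n,
                    "category": a.category,
                    "repeat_class": a.repeat_class,
                    "repeat_family": a.repeat_family,
                    "gene_subfeature": a.gene_subfeature,
                    "orientation": a.orientation,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tag",
            "library",
            "count",
            "category",
            "repeat_class",
            "repeat_family",
            "gene_subfeature",
            "orientation",
        ],
    )


def summarize_categories(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Category composition, repeat-class and gene-subfeature breakdowns.

    Composition is reported both read-weighted and tag-weighted (it is not
    knowable which convention a given published composition used, so both
    are emitted).  Breakdowns carry sense/antisense read counts and their
    ratio; an empty antisense side is flagged with inf, an empty group nan.
    """
    cats = ["repeat", "gene", "intergenic"]
    if frame.empty:
        empty = pd.DataFrame(columns=cats)
        return {"composition_reads": empty, "composition_tags": empty,
                "repeat_breakdown": pd.DataFrame(), "gene_breakdown": pd.DataFrame()}

    by_reads = (
        frame.pivot_table(index="library", columns="category", values="count",
                          aggfunc="sum", fill_value=0)
        .reindex(columns=cats, fill_value=0)
    )
    pooled = by_reads.sum(axis=0).to_frame().T
    pooled.index = ["pooled"]
    by_reads = pd.concat([by_reads, pooled])
    comp_reads = by_reads.div(by_reads.sum(axis=1).replace(0, float("nan")), axis=0)

    per_tag = frame.drop_duplicates("tag")
    tag_counts = per_tag.groupby("category")["tag"].count().reindex(cats, fill_value=0)
    comp_tags = (tag_counts / max(tag_counts.sum(), 1)).to_frame().T
    comp_tags.index = ["pooled"]

    def breakdown(sub: pd.DataFrame, group_col: str) -> pd.DataFrame:
        if sub.empty:
            return pd.DataFrame(columns=["sense", "antisense", "ratio"])
        piv = sub.pivot_table(index=group_col, columns="orientation", values="count",
                              aggfunc="sum", fill_value=0)
        for col in ("sense", "antisense"):
            if col not in piv:
                piv[col] = 0
        piv = piv[["sense", "antisense"]]
        piv["ratio"] = [_ratio(s, a) for s, a in zip(piv["sense"], piv["antisense"])]
        return piv

    rep = breakdown(frame[frame.category == "repeat"], "repeat_class")
    rep = rep.reindex([c for c in REPEAT_CLASSES if c in rep.index])
    gene = breakdown(frame[frame.category == "gene"], "gene_subfeature")
    return {
        "composition_reads": comp_reads,
        "composition_tags": comp_tags,
        "repeat_breakdown": rep,
        "gene_breakdown": gene,
    }
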