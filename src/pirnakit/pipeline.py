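"""End-to-end orchestration: raw libraries -> report bundle.

Stages run in the analysis order: clean each library, collapse to unique
tags, place tags on the genome by exact matching, exclude ncRNA-derived
tags, categorise uniquely mapped piRNAs, compute biogenesis signatures,
call and quantify clusters, build expression matrices with top-N profiling
and two-library differential tables, and estimate the sequence-pool size.
Every product is written as a TSV/BED table with documented headers; a
rerun with the same inputs and seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import annotate as _annotate
from . import clusters as _clusters
from . import expression as _expression
from . import pool as _pool
from . import preprocess as _preprocess
from . import signatures as _signatures
from .align import build_index, map_tags, split_by_class
from .config import RunConfig
from .io import AnnotationRecord, GenomeSequence, read_annotations, read_genome, read_sequences

logger = logging.getLogger("pirnakit")

FLOAT_FORMAT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    config: RunConfig
    cleaning_stats: dict
    tags: list
    mapped: list  # piRNA-like mapped tags (ncRNA-excluded), unique + multi
    excluded_ncrna: list
    unmapped: list
    assignments: pd.DataFrame
    summaries: dict
    signature_table: pd.DataFrame
    base_matrix: pd.DataFrame
    ping_pong: object
    strand_bias_tables: dict
    clusters: list
    cluster_table: pd.DataFrame
    expression_matrix: pd.DataFrame
    top_matrix: pd.DataFrame
    dendrogram: object
    de_tables: dict
    pool_estimate: object
    library_totals: dict
    length_spectra: pd.DataFrame


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(
    config: RunConfig,
    genome: Sequence[GenomeSequence],
    annotations: Sequence[AnnotationRecord],
    reads_per_library: Mapping[str, Sequence[str]],
    de_contrasts: Optional[Sequence[tuple[str, str]]] = None,
) -> PipelineResult:
    """Run the complete analysis on in-memory inputs.

    ``reads_per_library`` maps library name -> raw read sequences (adapter
    still attached).  ``de_contrasts`` defaults to (adult male vs sugar-fed
    female) and (sugar-fed vs blood-fed female) when those libraries exist.
    """
    libs = [lib for lib in config.library_names if lib in reads_per_library]
    if not libs:
        raise StageError("stage 'preprocess' failed: no known libraries supplied")

    # ---- cleaning --------------------------------------------------------
    kept, stats = {}, {}
    for lib in libs:
        kept[lib], stats[lib] = _preprocess.clean_reads(
            reads_per_library[lib],
            config.adapter,
            adapter_min_overlap=config.adapter_min_overlap,
            keep_min=config.read_length_keep_min,
            length_lo=config.piRNA_length_min,
            length_hi=config.piRNA_length_max,
            homopolymer_min_run=config.homopolymer_min_run,
        )
        if not stats[lib].conserved():
            raise StageError(f"stage 'preprocess' failed: read accounting leak in {lib}")
    spectra = pd.DataFrame(
        {lib: pd.Series(dict(stats[lib].length_spectrum)) for lib in libs}
    ).fillna(0).astype(int).sort_index()
    spectra.index.name = "length_nt"

    tags = _preprocess.collapse_tags(kept)

    # ---- mapping ---------------------------------------------------------
    try:
        index = build_index(genome)
        mapped_all = map_tags(tags, index)
    except Exception as exc:
        raise StageError(f"stage 'map' failed: {exc}") from exc
    placed = [mt for mt in mapped_all if mt.n_hits > 0]
    unmapped = [mt for mt in mapped_all if mt.n_hits == 0]

    # ---- ncRNA exclusion -------------------------------------------------
    mapped, excluded = _preprocess.exclude_ncRNA(placed, annotations)
    unique, multi, _ = split_by_class(mapped)
    library_totals = {
        lib: sum(mt.tag.counts.get(lib, 0) for mt in mapped) for lib in libs
    }

    # ---- annotation ------------------------------------------------------
    try:
        feature_index = _annotate.FeatureIndex(annotations)
        assignments = _annotate.assign_all(unique, feature_index)
        frame = _annotate.assignments_frame(assignments, unique)
        summaries = _annotate.summarize_categories(frame)
    except Exception as exc:
        raise StageError(f"stage 'annotate' failed: {exc}") from exc

    # ---- signatures ------------------------------------------------------
    try:
        signature_table = _signatures.signature_summary(unique, libs)
        base_matrix = _signatures.base_composition(
            [(mt.tag.sequence, mt.tag.total_count) for mt in unique]
        ).matrix
        ping_pong = _signatures.ping_pong_profile(unique)
        bias_tables = {
            "category": _signatures.strand_bias(frame, "category"),
            "repeat_class": _signatures.strand_bias(frame, "repeat_class"),
            "gene_subfeature": _signatures.strand_bias(frame, "gene_subfeature"),
            "library": _signatures.strand_bias(frame, "library"),
        }
    except Exception as exc:
        raise StageError(f"stage 'signatures' failed: {exc}") from exc

    # ---- clusters --------------------------------------------------------
    try:
        stream = _clusters.eligible_reads(mapped, config.cluster_min_support_reads)
        called = _clusters.call_clusters(
            stream, genome, config.cluster_window,
            config.cluster_min_sequences, config.cluster_merge_gap,
        )
        counts_by_seq = {mt.tag.sequence: dict(mt.tag.counts) for mt in mapped}
        called = _clusters.quantify_clusters(
            called, counts_by_seq, library_totals, config.cluster_min_support_reads
        )
        for cl in called:
            cl.strandness = _clusters.type_strandness(cl, stream)
            _clusters.cluster_content(cl, annotations)
        cluster_table = _clusters.clusters_frame(called, libs)
    except Exception as exc:
        raise StageError(f"stage 'clusters' failed: {exc}") from exc

    # ---- expression ------------------------------------------------------
    try:
        tag_ids = {mt.tag.sequence: f"tag_{i + 1}" for i, mt in enumerate(mapped)}
        counts = pd.DataFrame(
            [[mt.tag.counts.get(lib, 0) for lib in libs] for mt in mapped],
            index=[tag_ids[mt.tag.sequence] for mt in mapped],
            columns=libs,
        )
        matrix = _expression.tpm_matrix(counts, library_totals)
        top = _expression.top_n_union(matrix, config.top_n_per_stage)
        dendrogram = (
            _expression.hierarchical_cluster(top) if len(top) >= 2 else None
        )
        if de_contrasts is None:
            de_contrasts = [
                pair for pair in (
                    ("adult_male", "sugarfed_female"),
                    ("sugarfed_female", "bloodfed_female"),
                ) if pair[0] in libs and pair[1] in libs
            ]
        de_tables = {
            f"{a}_vs_{b}": _expression.de_table(
                counts, a, b,
                total_a=library_totals[a], total_b=library_totals[b],
                alpha=config.de_alpha, min_log2_ratio=config.de_min_log2_ratio,
            )
            for a, b in de_contrasts
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'expression' failed: {exc}") from exc

    # ---- pool size -------------------------------------------------------
    try:
        pool_estimate = _pool.pool_summary([mt.tag for mt in mapped], libs)
    except Exception as exc:
        raise StageError(f"stage 'pool' failed: {exc}") from exc

    return PipelineResult(
        config=config,
        cleaning_stats=stats,
        tags=tags,
        mapped=mapped,
        excluded_ncrna=excluded,
        unmapped=unmapped,
        assignments=frame,
        summaries=summaries,
        signature_table=signature_table,
        base_matrix=base_matrix,
        ping_pong=ping_pong,
        strand_bias_tables=bias_tables,
        clusters=called,
        cluster_table=cluster_table,
        expression_matrix=matrix,
        top_matrix=top,
        dendrogram=dendrogram,
        de_tables=de_tables,
        pool_estimate=pool_estimate,
        library_totals=library_totals,
        length_spectra=spectra,
    )


#: report tables the bundle always contains
REPORT_FILES = (
    "length_spectrum.tsv",
    "category_composition_reads.tsv",
    "category_composition_tags.tsv",
    "repeat_breakdown.tsv",
    "gene_breakdown.tsv",
    "signature_summary.tsv",
    "base_composition.tsv",
    "ping_pong_histogram.tsv",
    "ping_pong_bases.tsv",
    "strand_bias.tsv",
    "clusters.bed",
    "clusters.tsv",
    "expression_matrix.tsv",
    "top_expression_matrix.tsv",
    "expression_groups.tsv",
    "dendrogram.nwk",
    "pool_size.tsv",
    "mapping_summary.tsv",
    "run_log.txt",
)


def write_report(result: PipelineResult, out_dir, log_lines: Sequence[str] = ()) -> None:
    """Write the full report bundle (TSV tables, BED, Newick, log)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str, index_label=None) -> None:
        df.to_csv(out / name, sep="\t", float_format=FLOAT_FORMAT,
                  index_label=index_label)

    tsv(result.length_spectra, "length_spectrum.tsv")
    tsv(result.summaries["composition_reads"], "category_composition_reads.tsv", "library")
    tsv(result.summaries["composition_tags"], "category_composition_tags.tsv", "weighting")
    tsv(result.summaries["repeat_breakdown"], "repeat_breakdown.tsv", "repeat_class")
    tsv(result.summaries["gene_breakdown"], "gene_breakdown.tsv", "gene_subfeature")
    tsv(result.signature_table, "signature_summary.tsv")
    tsv(result.base_matrix, "base_composition.tsv", "position")
    tsv(result.ping_pong.histogram.to_frame(), "ping_pong_histogram.tsv", "overlap_nt")
    tsv(result.ping_pong.base_by_distance, "ping_pong_bases.tsv", "overlap_nt")
    bias = pd.concat(result.strand_bias_tables, names=["grouping", "group"])
    tsv(bias, "strand_bias.tsv")
    _clusters.write_clusters_bed(result.clusters, out / "clusters.bed")
    result.cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False,
                                float_format=FLOAT_FORMAT)
    tsv(result.expression_matrix, "expression_matrix.tsv", "tag_id")
    tsv(result.top_matrix, "top_expression_matrix.tsv", "tag_id")
    if result.dendrogram is not None:
        (out / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n")
        tsv(result.dendrogram.groups.to_frame(), "expression_groups.tsv", "tag_id")
    else:
        (out / "dendrogram.nwk").write_text(";\n")
        tsv(pd.DataFrame(columns=["group"]), "expression_groups.tsv", "tag_id")
    for name, table in result.de_tables.items():
        tsv(table, f"de_{name}.tsv")
    pool_df = result.pool_estimate.pairwise.copy()
    summary_row = pd.DataFrame([{
        "lib_i": "summary", "lib_j": "median/min/max",
        "n_i": "", "n_j": "", "m_ij": "",
        "estimate": f"{result.pool_estimate.point:.6g};"
                    f"{result.pool_estimate.minimum:.6g};"
                    f"{result.pool_estimate.maximum:.6g}",
    }])
    pd.concat([pool_df, summary_row], ignore_index=True).to_csv(
        out / "pool_size.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    mapping_rows = []
    for lib in result.library_totals:
        st = result.cleaning_stats[lib]
        mapping_rows.append({
            "library": lib,
            "n_input_reads": st.n_input,
            "n_kept_reads": st.n_kept,
            "n_adapter_dropped": st.n_adapter_dropped,
            "n_with_N": st.n_with_n,
            "n_length_dropped": st.n_length_dropped,
            "n_homopolymer_dropped": st.n_homopolymer_dropped,
            "genome_mapped_piRNA_reads": result.library_totals[lib],
        })
    pd.DataFrame(mapping_rows).to_csv(out / "mapping_summary.tsv", sep="\t", index=False)
    n_unique = sum(mt.mapping_class == "unique" for mt in result.mapped)
    n_multi = sum(mt.mapping_class == "multi" for mt in result.mapped)
    lines = list(log_lines) + [
        f"tags_total={len(result.tags)}",
        f"tags_mapped={len(result.mapped)}",
        f"tags_unique={n_unique}",
        f"tags_multi={n_multi}",
        f"tags_unmapped={len(result.unmapped)}",
        f"tags_ncRNA_excluded={len(result.excluded_ncrna)}",
        f"clusters_called={len(result.clusters)}",
    ]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def run_from_files(
    config: RunConfig,
    genome_path,
    annotation_paths: Sequence,
    fastq_per_library: Mapping[str, object],
    out_dir=None,
) -> PipelineResult:
    """File-based entry point: read inputs, run, optionally write the bundle."""
    genome = read_genome(genome_path)
    annotations: list[AnnotationRecord] = []
    for path in annotation_paths:
        annotations.extend(read_annotations(path))
    reads = {
        lib: [rec[1] for rec in read_sequences(path)]
        for lib, path in fastq_per_library.items()
    }
    result = run_pipeline(config, genome, annotations, reads)
    if out_dir is not None:
        write_report(result, out_dir)
    return result
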