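"""Window-based cluster calling: thresholds, merging, trimming, typing."""

import numpy as np
import pytest

from pirnakit.align import MappedTag
from pirnakit.clusters import (
    call_clusters,
    cluster_content,
    eligible_reads,
    quantify_clusters,
    type_strandness,
)
from pirnakit.io import AnnotationRecord, GenomeSequence
from pirnakit.preprocess import UniqueTag


def genome(length=50000, contig="c1"):
    return [GenomeSequence(contig, "A" * length)]


def stream_of(entries):
    """entries: (start, length, strand, seq_id[, contig])"""
    out = []
    for e in entries:
        start, length, strand, seq = e[:4]
        contig = e[4] if len(e) > 4 else "c1"
        out.append((contig, start, start + length, strand, seq))
    return sorted(out, key=lambda x: (x[0], x[1], x[2], x[3]))


def brute_force_clusters(stream, contig_len, window=5000, min_sequences=10,
                         merge_gap=20000):
    """Independent per-bp window enumeration, merge and trim."""
    by_contig = {}
    for contig, start, end, _strand, seq in stream:
        by_contig.setdefault(contig, []).append((start, end, seq))
    results = []
    for contig in sorted(by_contig):
        placements = by_contig[contig]
        S = max(contig_len - window, 0)
        cover = np.zeros(S + 1 + window, dtype=bool)
        counts = np.zeros(S + 2, dtype=int)
        per_seq = {}
        for start, end, seq in placements:
            a = max(start - window + 1, 0)
            b = min(end - 1, S)
            if a <= b:
                per_seq.setdefault(seq, []).append((a, b))
        for ivs in per_seq.values():
            mask = np.zeros(S + 1, dtype=bool)
            for a, b in ivs:
                mask[a:b + 1] = True
            counts[:S + 1] += mask
        qualifying = counts[:S + 1] >= min_sequences
        for s in np.flatnonzero(qualifying):
            cover[s:s + window] = True
        # merged genomic regions of qualifying windows
        regions = []
        in_r = False
        for i, c in enumerate(cover):
            if c and not in_r:
                a0, in_r = i, True
            elif not c and in_r:
                regions.append((a0, i))
                in_r = False
        if in_r:
            regions.append((a0, len(cover)))
        merged = []
        for a, b in regions:
            if merged and a - merged[-1][1] < merge_gap:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        for a, b in merged:
            inside = [(s, e, q) for s, e, q in placements if s < b and e > a]
            results.append((contig, min(s for s, _, _ in inside),
                            max(e for _, e, _ in inside),
                            len({q for _, _, q in inside})))
    return results


def called_tuples(clusters):
    return [(c.contig, c.start, c.end, c.n_distinct_piRNAs) for c in clusters]


class TestThresholdBoundaries:
    def test_twelve_distinct_tags_make_one_trimmed_cluster(self):
        entries = [(1000 + 250 * i, 26, "+", f"s{i}") for i in range(12)]
        (cl,) = call_clusters(stream_of(entries), genome())
        assert (cl.start, cl.end) == (1000, 1000 + 250 * 11 + 26)
        assert cl.n_distinct_piRNAs == 12

    def test_nine_distinct_tags_make_no_cluster(self):
        entries = [(1000 + 250 * i, 26, "+", f"s{i}") for i in range(9)]
        assert call_clusters(stream_of(entries), genome()) == []

    def test_ten_distinct_is_the_boundary(self):
        entries = [(1000 + 250 * i, 26, "+", f"s{i}") for i in range(10)]
        assert len(call_clusters(stream_of(entries), genome())) == 1

    def test_duplicate_placements_of_one_sequence_count_once(self):
        entries = [(1000 + 200 * i, 26, "+", "same") for i in range(12)]
        assert call_clusters(stream_of(entries), genome()) == []

    def test_windows_15kb_apart_merge_25kb_apart_do_not(self):
        def block(at, tag_prefix):
            return [(at + 100 * i, 26, "+", f"{tag_prefix}{i}") for i in range(12)]
        g = genome(90000)
        near = stream_of(block(1000, "a") + block(1000 + 15000, "b"))
        assert len(call_clusters(near, g)) == 1
        far = stream_of(block(1000, "a") + block(1000 + 30000, "b"))
        assert len(call_clusters(far, g)) == 2

    def test_unknown_contig_is_an_error(self):
        with pytest.raises(ValueError, match="c9"):
            call_clusters([("c9", 0, 26, "+", "s")], genome())


class TestSupportFilter:
    def make_mapped(self, total):
        tag = UniqueTag("ACGT" * 7)
        tag.counts["E"] = total
        return MappedTag(tag, [("c1", 100, 128, "+"), ("c1", 900, 928, "+"),
                               ("c1", 5000, 5028, "-")])

    def test_tag_above_prefilter_contributes_every_placement(self):
        stream = eligible_reads([self.make_mapped(250)], 200)
        assert len(stream) == 3

    def test_tag_below_prefilter_excluded(self):
        assert eligible_reads([self.make_mapped(150)], 200) == []

    def test_cluster_support_boundary_199_vs_200(self):
        entries = [(1000 + 250 * i, 26, "+", f"s{i}") for i in range(10)]
        clusters = call_clusters(stream_of(entries), genome())
        counts_low = {f"s{i}": {"E": 19 + (i == 0)} for i in range(10)}   # 191
        counts_199 = {f"s{i}": {"E": 20} for i in range(10)}
        counts_199["s0"] = {"E": 19}                                      # 199
        counts_200 = {f"s{i}": {"E": 20} for i in range(10)}              # 200
        totals = {"E": 10000}
        assert quantify_clusters([c for c in clusters], counts_199, totals, 200) == []
        import copy
        kept = quantify_clusters(copy.deepcopy(clusters), counts_200, totals, 200)
        assert len(kept) == 1
        assert kept[0].support_reads_total == 200

    def test_tpm_arithmetic(self):
        entries = [(1000 + 250 * i, 26, "+", f"s{i}") for i in range(10)]
        clusters = call_clusters(stream_of(entries), genome())
        counts = {f"s{i}": {"E": 50} for i in range(10)}
        (cl,) = quantify_clusters(clusters, counts, {"E": 1_000_000}, 200)
        assert cl.tpm_per_library["E"] == pytest.approx(500.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_bp_enumeration_on_random_placements(self, seed):
        rng = np.random.default_rng(seed)
        L = 50000
        entries = []
        # a few dense patches plus scattered background
        for patch in range(rng.integers(1, 4)):
            at = int(rng.integers(0, L - 6000))
            n = int(rng.integers(5, 25))
            for i in range(n):
                entries.append((min(at + int(rng.integers(0, 4000)), L - 30),
                                int(rng.integers(24, 31)), "+",
                                f"p{patch}_{i}"))
        for i in range(int(rng.integers(10, 40))):
            entries.append((int(rng.integers(0, L - 30)),
                            int(rng.integers(24, 31)),
                            "-" if rng.random() < 0.5 else "+", f"bg{i}"))
        stream = stream_of(entries)
        called = called_tuples(call_clusters(stream, genome(L)))
        assert called == brute_force_clusters(stream, L)

    def test_monotone_in_min_sequences(self):
        rng = np.random.default_rng(99)
        entries = [(int(rng.integers(0, 40000)), 26, "+", f"s{i}")
                   for i in range(200)]
        stream = stream_of(entries)
        n_prev = None
        for min_seq in (5, 10, 15, 20):
            n = len(call_clusters(stream, genome(), min_sequences=min_seq))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestStrandnessAndContent:
    def cluster_from(self, entries, g=None):
        (cl,) = call_clusters(stream_of(entries), g or genome())
        return cl, stream_of(entries)

    def test_all_plus_is_plus_only(self):
        cl, stream = self.cluster_from(
            [(1000 + 200 * i, 26, "+", f"s{i}") for i in range(12)])
        assert type_strandness(cl, stream) == "plus_only"

    def test_divergent_non_overlapping(self):
        entries = [(1000 + 100 * i, 26, "-", f"m{i}") for i in range(10)]
        entries += [(3000 + 100 * i, 26, "+", f"p{i}") for i in range(10)]
        cl, stream = self.cluster_from(entries)
        assert type_strandness(cl, stream) == "divergent_non_overlapping"

    def test_interleaved_strands_are_mixed_overlapping(self):
        entries = [(1000 + 100 * i, 26, "+-"[i % 2], f"s{i}") for i in range(14)]
        cl, stream = self.cluster_from(entries)
        assert type_strandness(cl, stream) == "mixed_overlapping"

    def test_content_flags(self):
        cl, _ = self.cluster_from(
            [(1000 + 200 * i, 26, "+", f"s{i}") for i in range(12)])
        annotations = [
            AnnotationRecord("c1", 1500, 2000, "+", "repeat",
                             repeat_class="LTR", repeat_family="Gypsy"),
            AnnotationRecord("c1", 40000, 45000, "+", "gene", record_id="g1"),
        ]
        cluster_content(cl, annotations)
        assert cl.contains_TE and cl.te_list == ["LTR/Gypsy"]
        assert not cl.contains_gene

    def test_gene_intron_only_overlap_counts_as_gene(self):
        cl, _ = self.cluster_from(
            [(1000 + 200 * i, 26, "+", f"s{i}") for i in range(12)])
        annotations = [
            AnnotationRecord("c1", 2000, 2500, "+", "gene", record_id="g1"),
            AnnotationRecord("c1", 2000, 2100, "+", "exon", parent_id="g1"),
        ]
        cluster_content(cl, annotations)
        assert cl.contains_gene
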