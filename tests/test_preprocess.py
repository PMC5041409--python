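"""Read cleaning and tag collapsing."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from pirnakit.align import MappedTag
from pirnakit.io import AnnotationRecord
from pirnakit.preprocess import (
    UniqueTag,
    clean_reads,
    collapse_tags,
    exclude_ncRNA,
    filter_homopolymers,
    has_homopolymer,
    select_lengths,
    trim_adapter,
)

ADAPTER = "TCGTATGCCGTCTTCTGCTTGT"
dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


class TestTrimAdapter:
    def test_insert_plus_full_adapter_returns_insert(self):
        insert = "ACGTACGTACGTACGTACGTACGTAC"
        assert trim_adapter(insert + ADAPTER, ADAPTER) == insert

    def test_truncated_adapter_suffix_removed(self):
        insert = "ACGTACGTACGTACGTACGTACGTAC"
        read = (insert + ADAPTER)[:36]  # machine-length read, partial adapter
        assert trim_adapter(read, ADAPTER) == insert

    def test_no_match_returns_read_unchanged(self):
        read = "AAACCCGGGTTTAAACCCGGGTTTAAA"
        assert trim_adapter(read, ADAPTER) == read

    def test_whole_read_is_adapter_gives_empty(self):
        assert trim_adapter(ADAPTER, ADAPTER) == ""

    def test_match_below_min_overlap_ignored(self):
        read = "AAACCCGGGTTTAAACCCGGG" + ADAPTER[:5]
        assert trim_adapter(read, ADAPTER, min_overlap=6) == read

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT", "")


class TestLengthSelection:
    def test_boundaries_inclusive(self):
        reads = ["A" * 23, "C" * 24, "G" * 30, "T" * 31]
        assert select_lengths(reads, 24, 30) == ["C" * 24, "G" * 30]

    def test_empty_input(self):
        assert select_lengths([], 24, 30) == []

    def test_lo_above_hi_is_error(self):
        with pytest.raises(ValueError):
            select_lengths(["ACGT"], 30, 24)

    def test_matches_one_line_oracle_on_random_reads(self):
        import random
        rnd = random.Random(11)
        reads = ["".join(rnd.choices("ACGT", k=rnd.randint(15, 35)))
                 for _ in range(1000)]
        assert select_lengths(reads, 24, 30) == [r for r in reads if 24 <= len(r) <= 30]


class TestHomopolymerFilter:
    def test_eight_run_removed(self):
        assert filter_homopolymers(["ACG" + "A" * 8 + "CGTACGTACG"]) == []

    def test_seven_run_kept(self):
        read = "ACG" + "T" * 7 + "CGTACGTACG"
        assert filter_homopolymers([read]) == [read]

    def test_run_at_five_prime_end_removed(self):
        assert filter_homopolymers(["C" * 8 + "ACGTACGTACGTACGT"]) == []

    @given(st.lists(dna, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_filter_idempotent(self, reads):
        once = filter_homopolymers(reads)
        assert filter_homopolymers(once) == once

    @given(st.lists(dna, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_length_selection_idempotent(self, reads):
        once = select_lengths(reads, 24, 30)
        assert select_lengths(once, 24, 30) == once

    def test_min_run_below_two_rejected(self):
        with pytest.raises(ValueError):
            has_homopolymer("ACGT", 1)


class TestCollapse:
    def test_three_identical_reads_one_library(self):
        (tag,) = collapse_tags({"E": ["ACGT" * 6] * 3})
        assert tag.counts == Counter({"E": 3})
        assert tag.total_count == 3

    def test_same_sequence_across_libraries_is_one_tag(self):
        (tag,) = collapse_tags({"E": ["ACGT" * 6] * 2, "L": ["ACGT" * 6]})
        assert tag.counts == Counter({"E": 2, "L": 1})

    def test_matches_dictionary_count_oracle(self):
        import random
        rnd = random.Random(5)
        pool = ["".join(rnd.choices("ACGT", k=26)) for _ in range(40)]
        per_lib = {
            lib: [rnd.choice(pool) for _ in range(500)] for lib in ("E", "L", "P")
        }
        oracle: dict[str, Counter] = {}
        for lib, reads in per_lib.items():
            for r in reads:
                oracle.setdefault(r, Counter())[lib] += 1
        tags = collapse_tags(per_lib)
        assert {t.sequence: t.counts for t in tags} == oracle
        assert sum(t.total_count for t in tags) == 1500


def _mapped(seq, placements):
    tag = UniqueTag(seq)
    tag.counts["E"] = 1
    return MappedTag(tag, placements)


class TestNcRNAExclusion:
    annotations = [
        AnnotationRecord("c1", 100, 200, "+", "miRNA"),
        AnnotationRecord("c1", 500, 600, "+", "tRNA"),
    ]

    def test_tag_inside_mirna_excluded_with_reason(self):
        mt = _mapped("A" * 26, [("c1", 120, 146, "+")])
        kept, excluded = exclude_ncRNA([mt], self.annotations)
        assert kept == []
        assert excluded[0][1] == "miRNA"

    def test_intergenic_tag_retained(self):
        mt = _mapped("A" * 26, [("c1", 3000, 3026, "+")])
        kept, excluded = exclude_ncRNA([mt], self.annotations)
        assert kept == [mt] and excluded == []

    def test_any_placement_rule(self):
        mt = _mapped("A" * 26, [("c1", 3000, 3026, "+"), ("c1", 580, 606, "-")])
        kept, excluded = exclude_ncRNA([mt], self.annotations)
        assert kept == [] and excluded[0][1] == "tRNA"

    def test_missing_annotation_keeps_everything(self):
        mt = _mapped("A" * 26, [("c1", 120, 146, "+")])
        kept, excluded = exclude_ncRNA([mt], [])
        assert kept == [mt] and excluded == []


def test_clean_reads_conservation_accounting():
    import random
    rnd = random.Random(3)
    reads = []
    for _ in range(2000):
        kind = rnd.random()
        if kind < 0.1:
            reads.append(ADAPTER[:30])  # pure adapter
        elif kind < 0.2:
            insert = "".join(rnd.choices("ACGT", k=26))
            reads.append((insert[:10] + "N" + insert[11:] + ADAPTER)[:36])
        elif kind < 0.3:
            reads.append(("ACG" + "T" * 9 + "".join(rnd.choices("ACGT", k=14)) + ADAPTER)[:36])
        else:
            insert = "".join(rnd.choices("ACGT", k=rnd.randint(18, 32)))
            reads.append((insert + ADAPTER)[:36])
    kept, stats = clean_reads(reads, ADAPTER)
    assert stats.conserved()
    assert stats.n_kept == len(kept)
    assert stats.n_input == 2000
    assert all(24 <= len(r) <= 30 for r in kept)
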