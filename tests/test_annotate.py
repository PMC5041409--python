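"""Category assignment precedence, orientation, and composition summaries."""

import math

import pytest

from pirnakit.align import MappedTag
from pirnakit.annotate import (
    FeatureIndex,
    assign_all,
    assign_category,
    assignments_frame,
    summarize_categories,
)
from pirnakit.io import AnnotationRecord
from pirnakit.preprocess import UniqueTag

ANNOTATIONS = [
    AnnotationRecord("c1", 1000, 2000, "+", "repeat",
                     repeat_class="LTR", repeat_family="Gypsy"),
    AnnotationRecord("c1", 5000, 9000, "+", "gene", record_id="g1"),
    AnnotationRecord("c1", 5000, 5500, "+", "exon", parent_id="g1"),
    AnnotationRecord("c1", 5000, 5120, "+", "five_prime_UTR", parent_id="g1"),
    AnnotationRecord("c1", 5120, 5500, "+", "CDS", parent_id="g1"),
    AnnotationRecord("c1", 5500, 7000, "+", "intron", parent_id="g1"),
    AnnotationRecord("c1", 7000, 9000, "+", "exon", parent_id="g1"),
    AnnotationRecord("c1", 7000, 8880, "+", "CDS", parent_id="g1"),
    AnnotationRecord("c1", 8880, 9000, "+", "three_prime_UTR", parent_id="g1"),
    # a repeat inside the intron exercises repeat > gene precedence
    AnnotationRecord("c1", 6000, 6400, "-", "repeat",
                     repeat_class="LINE", repeat_family="R1"),
]


def mapped(seq_len, contig, start, strand, counts=None):
    tag = UniqueTag("A" * seq_len)
    tag.counts.update(counts or {"E": 1})
    return MappedTag(tag, [(contig, start, start + seq_len, strand)])


@pytest.fixture(scope="module")
def index():
    return FeatureIndex(ANNOTATIONS)


class TestAssignment:
    def test_repeat_sense(self, index):
        a = assign_category(mapped(26, "c1", 1100, "+"), index)
        assert (a.category, a.repeat_class, a.repeat_family, a.orientation) == (
            "repeat", "LTR", "Gypsy", "sense")

    def test_cds_antisense(self, index):
        a = assign_category(mapped(26, "c1", 5200, "-"), index)
        assert (a.category, a.gene_subfeature, a.orientation) == (
            "gene", "CDS", "antisense")

    def test_intron(self, index):
        a = assign_category(mapped(26, "c1", 5600, "+"), index)
        assert (a.category, a.gene_subfeature) == ("gene", "intron")

    def test_intergenic(self, index):
        a = assign_category(mapped(26, "c1", 30000, "+"), index)
        assert (a.category, a.orientation) == ("intergenic", "n/a")

    def test_repeat_inside_intron_counts_as_repeat(self, index):
        a = assign_category(mapped(26, "c1", 6100, "+"), index)
        assert a.category == "repeat"
        assert a.repeat_class == "LINE"
        assert a.orientation == "antisense"  # + tag over a - repeat

    def test_cds_beats_utr_on_junction(self, index):
        # spans the 5'UTR/CDS boundary; CDS has precedence
        a = assign_category(mapped(26, "c1", 5110, "+"), index)
        assert a.gene_subfeature == "CDS"

    def test_multi_mapping_tag_rejected(self, index):
        tag = UniqueTag("A" * 26)
        mt = MappedTag(tag, [("c1", 0, 26, "+"), ("c1", 50, 76, "+")])
        with pytest.raises(ValueError):
            assign_category(mt, index)


def uniq_seq(i: int, length: int = 26) -> str:
    """Deterministic distinct DNA sequence per index (base-4 encoding)."""
    digits = []
    n = i
    for _ in range(6):
        digits.append("ACGT"[n % 4])
        n //= 4
    return ("ACGT" * 7)[: length - 6] + "".join(digits)


class TestSummaries:
    def build_frame(self, specs):
        mts = []
        for i, (start, strand, counts) in enumerate(specs):
            mt = mapped(26, "c1", start, strand, counts)
            mt.tag.sequence = uniq_seq(i)
            mts.append(mt)
        assigns = assign_all(mts, FeatureIndex(ANNOTATIONS))
        return assignments_frame(assigns, mts)

    def test_fractions_sum_to_one(self):
        frame = self.build_frame([
            (1100, "+", {"E": 10}), (5200, "+", {"E": 5}), (30000, "+", {"E": 5}),
        ])
        comp = summarize_categories(frame)["composition_reads"]
        assert comp.loc["E"].sum() == pytest.approx(1.0)
        assert comp.loc["pooled", "repeat"] == pytest.approx(0.5)

    def test_all_sense_gives_infinite_ratio(self):
        frame = self.build_frame([(1100, "+", {"E": 4}), (1200, "+", {"E": 6})])
        rep = summarize_categories(frame)["repeat_breakdown"]
        assert math.isinf(rep.loc["LTR", "ratio"])

    def test_single_antisense_read_gives_zero_ratio(self):
        frame = self.build_frame([(6100, "+", {"E": 1})])  # antisense over - LINE
        rep = summarize_categories(frame)["repeat_breakdown"]
        assert rep.loc["LINE", "ratio"] == 0.0


def test_orientation_antisymmetry_under_strand_flip():
    flipped = [
        AnnotationRecord(
            r.contig_id, r.start, r.end,
            {"+": "-", "-": "+", ".": "."}[r.strand],
            r.feature_kind, r.repeat_class, r.repeat_family, r.parent_id, r.record_id,
        )
        for r in ANNOTATIONS
    ]
    specs = [(1050, "+"), (1500, "-"), (5200, "+"), (6100, "-"), (7100, "+")]
    mts = [mapped(26, "c1", s, st, {"E": i + 1}) for i, (s, st) in enumerate(specs)]
    for i, mt in enumerate(mts):
        mt.tag.sequence = uniq_seq(i)
    base = assignments_frame(assign_all(mts, FeatureIndex(ANNOTATIONS)), mts)
    flip = assignments_frame(assign_all(mts, FeatureIndex(flipped)), mts)
    orient_swap = {"sense": "antisense", "antisense": "sense", "n/a": "n/a"}
    assert list(flip.orientation) == [orient_swap[o] for o in base.orientation]


def test_truth_category_recovery_on_synthetic_bundle(bundle):
    """Uniquely mapped primary reads land in their planted category."""
    result = bundle["result"]
    truth = bundle["truth"]
    label_by_seq = {}
    for loc in truth.loci:
        label_by_seq[loc.sequence] = loc.category
    unique = [mt for mt in result.mapped if mt.mapping_class == "unique"]
    index = FeatureIndex(bundle["annotations"])
    checked = correct = 0
    for mt in unique:
        planted = label_by_seq.get(mt.tag.sequence)
        if planted is None or planted == "ncRNA":
            continue
        checked += 1
        a = assign_category(mt, index)
        correct += a.category == planted
    assert checked > 500
    assert correct / checked > 0.98
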