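"""Read annotation, fragment classification, isoacceptor aggregation."""

import numpy as np
import pytest

from mirgba.annotation import (
    AnnotationRecord,
    AnnotationSet,
    FragmentClass,
    FragmentThresholds,
    ReadRecord,
    annotate_read,
    class_fractions,
    classify_trna_fragment,
    isoacceptor_counts,
    length_histogram,
    parse_isoacceptor,
)


@pytest.fixture
def simple_annotations():
    return AnnotationSet(
        [
            AnnotationRecord("chr1", 100, 124, "+", "mir-x", "miRNA"),
            AnnotationRecord("chr1", 300, 372, "+", "tRNA-His-GTG-1-1", "tRNA"),
            AnnotationRecord("chr1", 500, 572, "-", "tRNA-Cys-GCA-1-1", "tRNA"),
            AnnotationRecord("chr1", 700, 850, "+", "rRNA-x", "rRNA"),
        ]
    )


class TestLengthHistogram:
    def test_empty(self):
        assert length_histogram([]) == {}

    def test_direct_count(self):
        reads = [
            ReadRecord("chr1", 0, 21, "+", "a"),
            ReadRecord("chr1", 50, 71, "+", "b"),
            ReadRecord("chr1", 100, 131, "+", "c"),
        ]
        assert length_histogram(reads) == {21: 2, 31: 1}


class TestAnnotateRead:
    def test_full_overlap_mirna(self, simple_annotations):
        read = ReadRecord("chr1", 101, 123, "+", "r")
        assert annotate_read(read, simple_annotations) == "miRNA"

    def test_antisense_read_unannotated(self, simple_annotations):
        read = ReadRecord("chr1", 101, 123, "-", "r")
        assert annotate_read(read, simple_annotations) == "unannotated"

    def test_maximal_overlap_wins_over_priority(self):
        """18 nt tRNA overlap beats 10 nt miRNA overlap despite priority."""
        ann = AnnotationSet(
            [
                AnnotationRecord("chr1", 100, 130, "+", "mir", "miRNA"),
                AnnotationRecord("chr1", 120, 200, "+", "tRNA-His-GTG-1-1", "tRNA"),
            ]
        )
        read = ReadRecord("chr1", 120, 148, "+", "r")  # 10 nt in miRNA, 28 in tRNA
        assert annotate_read(read, ann) == "tRNA"

    def test_tie_broken_by_class_priority(self):
        ann = AnnotationSet(
            [
                AnnotationRecord("chr1", 100, 200, "+", "t", "tRNA"),
                AnnotationRecord("chr1", 100, 200, "+", "m", "miRNA"),
            ]
        )
        read = ReadRecord("chr1", 120, 142, "+", "r")
        assert annotate_read(read, ann) == "miRNA"

    def test_order_invariance(self):
        records = [
            AnnotationRecord("chr1", 100, 200, "+", "t", "tRNA"),
            AnnotationRecord("chr1", 150, 260, "+", "m", "miRNA"),
            AnnotationRecord("chr1", 90, 180, "+", "s", "snoRNA"),
        ]
        read = ReadRecord("chr1", 140, 175, "+", "r")
        calls = {
            annotate_read(read, AnnotationSet(order))
            for order in (records, records[::-1], records[1:] + records[:1])
        }
        assert len(calls) == 1


class TestClassFractions:
    def test_direct_arithmetic(self):
        ann = AnnotationSet(
            [
                AnnotationRecord("chr1", 0, 72, "+", "tRNA-His-GTG-1-1", "tRNA"),
                AnnotationRecord("chr1", 200, 224, "+", "m", "miRNA"),
            ]
        )
        reads = [ReadRecord("chr1", 0, 31, "+", f"t{i}") for i in range(3)]
        reads += [ReadRecord("chr1", 200, 222, "+", "m1")]
        fr = class_fractions(reads, ann)
        assert fr == {"miRNA": 0.25, "tRNA": 0.75}

    def test_all_mirna(self, simple_annotations):
        reads = [ReadRecord("chr1", 101, 123, "+", "r")]
        fr = class_fractions(reads, simple_annotations)
        assert fr == {"miRNA": 1.0, "tRNA": 0.0}

    def test_no_annotated_reads_error(self, simple_annotations):
        reads = [ReadRecord("chr2", 0, 30, "+", "r")]
        with pytest.raises(ValueError, match="no reads"):
            class_fractions(reads, simple_annotations)

    def test_conservation_over_classes(self, simple_annotations):
        """Class counts plus unannotated account for every read."""
        rng = np.random.default_rng(0)
        reads = [
            ReadRecord(
                "chr1", int(s), int(s) + int(l), rng.choice(["+", "-"]), f"r{i}"
            )
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 900, 200), rng.integers(16, 40, 200))
            )
        ]
        calls = [annotate_read(r, simple_annotations) for r in reads]
        assert len(calls) == len(reads)
        assert set(calls) <= {"miRNA", "tRNA", "rRNA", "unannotated"}


class TestFragmentClassification:
    TRNA = AnnotationRecord("chr1", 300, 372, "+", "tRNA-His-GTG-1-1", "tRNA")
    TRNA_MINUS = AnnotationRecord("chr1", 500, 572, "-", "tRNA-Cys-GCA-1-1", "tRNA")

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (300, 331, FragmentClass.five_prime_half),   # 31 nt at 5' end
            (302, 333, FragmentClass.five_prime_half),   # within 3 nt tolerance
            (341, 372, FragmentClass.three_prime_half),  # 31 nt at 3' end
            (300, 320, FragmentClass.five_prime_tRF),    # 20 nt at 5' end
            (352, 372, FragmentClass.three_prime_tRF),
            (320, 351, FragmentClass.other_tRNA_fragment),  # centred, unanchored
            (310, 338, FragmentClass.other_tRNA_fragment),  # 28 nt: no class size
        ],
    )
    def test_plus_strand_assignment(self, start, end, expected):
        read = ReadRecord("chr1", start, end, "+", "r")
        assert classify_trna_fragment(read, self.TRNA) is expected

    def test_minus_strand_five_prime_is_right_edge(self):
        read = ReadRecord("chr1", 541, 572, "-", "r")  # 31 nt at genomic right
        assert (
            classify_trna_fragment(read, self.TRNA_MINUS)
            is FragmentClass.five_prime_half
        )

    def test_partition_property(self):
        """Every overlapping read receives exactly one class."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            start = int(rng.integers(290, 370))
            length = int(rng.integers(16, 45))
            read = ReadRecord("chr1", start, start + length, "+", "r")
            if min(read.end, self.TRNA.end) - max(read.start, self.TRNA.start) <= 0:
                continue
            cls = classify_trna_fragment(read, self.TRNA)
            assert isinstance(cls, FragmentClass)

    def test_non_overlapping_rejected(self):
        read = ReadRecord("chr1", 0, 31, "+", "r")
        with pytest.raises(ValueError):
            classify_trna_fragment(read, self.TRNA)

    def test_custom_thresholds(self):
        read = ReadRecord("chr1", 305, 336, "+", "r")  # 5 nt off the terminus
        assert (
            classify_trna_fragment(read, self.TRNA)
            is FragmentClass.other_tRNA_fragment
        )
        loose = FragmentThresholds(anchor_tol=6)
        assert (
            classify_trna_fragment(read, self.TRNA, loose)
            is FragmentClass.five_prime_half
        )


class TestIsoacceptors:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("tRNA-His-GTG-1-1", ("His", "GTG")),
            ("chr1.trna5-HisGTG", ("His", "GTG")),
            ("tRNA-iMet-CAT-2-1", ("iMet", "CAT")),
            ("chr12.trna112-CysGCA", ("Cys", "GCA")),
            ("not-a-trna", None),
        ],
    )
    def test_parser_dialects(self, name, expected):
        assert parse_isoacceptor(name) == expected

    def test_five_prime_half_counting(self, simple_annotations):
        reads = [
            ReadRecord("chr1", 300, 331, "+", "a", sample="S1"),
            ReadRecord("chr1", 300, 332, "+", "b", sample="S1"),
            ReadRecord("chr1", 541, 572, "-", "c", sample="S1"),  # Cys 5' half
        ]
        mat, rejects = isoacceptor_counts(reads, simple_annotations)
        assert rejects == []
        assert mat.loc["His-GTG", "S1"] == 2
        assert mat.loc["Cys-GCA", "S1"] == 1

    def test_three_prime_reads_excluded(self, simple_annotations):
        reads = [ReadRecord("chr1", 341, 372, "+", "a")]  # 3' half
        mat, _ = isoacceptor_counts(reads, simple_annotations)
        assert mat.empty

    def test_unparseable_names_rejected_not_dropped(self):
        ann = AnnotationSet(
            [AnnotationRecord("chr1", 0, 72, "+", "weird-name", "tRNA")]
        )
        reads = [ReadRecord("chr1", 0, 31, "+", "a")]
        mat, rejects = isoacceptor_counts(reads, ann)
        assert rejects == ["weird-name"]
        assert mat.empty
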