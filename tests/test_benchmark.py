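"""Library recovery categories, per-base annotation and cleaning metrics."""

import math
import random

import pytest

from tecurate.benchmark import (
    Annotation,
    genome_confusion_matrix,
    library_benchmark,
    msa_cleaning_confusion,
    read_bed,
    read_repeatmasker_out,
    resolve_annotation_overlaps,
)
from tecurate.msa import Msa
from tecurate.synthetic import mutate_sequence, random_sequence

from conftest import msa_from


class TestGenomeConfusion:
    def test_hand_counted_kilobase_example(self):
        test = [Annotation("c", 100, 600, "TE")]
        ref = [Annotation("c", 0, 500, "TE")]
        counts, metrics = genome_confusion_matrix(test, ref, 1000)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (400, 100, 100, 400)
        for value in (metrics.sensitivity, metrics.specificity, metrics.accuracy, metrics.precision, metrics.f1):
            assert value == pytest.approx(0.8)
        assert metrics.fdr == pytest.approx(0.2)

    def test_self_comparison_is_perfect(self):
        ann = [Annotation("c", 10, 400, "TE"), Annotation("c", 500, 800, "TE")]
        counts, metrics = genome_confusion_matrix(ann, ann, 1000)
        assert metrics.sensitivity == 1.0 and metrics.precision == 1.0
        assert metrics.fdr == 0.0

    def test_empty_test_has_nan_precision(self):
        counts, metrics = genome_confusion_matrix([], [Annotation("c", 0, 100, "TE")], 1000)
        assert counts.tp == 0
        assert metrics.sensitivity == 0.0
        assert math.isnan(metrics.precision)

    def test_counts_conserve_genome_length(self):
        rng = random.Random(3)
        for _ in range(25):
            length = rng.randint(50, 2000)

            def anns():
                out = []
                for _ in range(rng.randint(0, 6)):
                    s = rng.randint(0, length - 2)
                    out.append(Annotation("c", s, rng.randint(s + 1, length), "TE"))
                return out

            counts, _ = genome_confusion_matrix(anns(), anns(), length)
            assert counts.total == length

    def test_swap_symmetry(self):
        rng = random.Random(4)
        length = 1500

        def anns():
            out = []
            for _ in range(rng.randint(1, 5)):
                s = rng.randint(0, length - 2)
                out.append(Annotation("c", s, rng.randint(s + 1, length), "TE"))
            return out

        for _ in range(20):
            a, b = anns(), anns()
            c1, m1 = genome_confusion_matrix(a, b, length)
            c2, m2 = genome_confusion_matrix(b, a, length)
            assert (c1.fp, c1.fn) == (c2.fn, c2.fp)
            if not math.isnan(m1.sensitivity) and not math.isnan(m2.precision):
                assert m1.sensitivity == pytest.approx(m2.precision)

    def test_per_type_scope(self):
        test = [Annotation("c", 0, 100, "LTR"), Annotation("c", 200, 300, "LINE")]
        ref = [Annotation("c", 0, 100, "LTR"), Annotation("c", 200, 300, "LTR")]
        counts, _ = genome_confusion_matrix(test, ref, 400, te_type="LTR")
        assert (counts.tp, counts.fn, counts.fp) == (100, 100, 0)

    def test_interval_beyond_genome_rejected(self):
        with pytest.raises(ValueError):
            genome_confusion_matrix([Annotation("c", 0, 2000, "TE")], [], 1000)


class TestOverlapResolution:
    def test_same_type_merge(self):
        out = resolve_annotation_overlaps(
            [Annotation("c", 0, 100, "LTR"), Annotation("c", 50, 150, "LTR")]
        )
        assert out == [Annotation("c", 0, 150, "LTR")]

    def test_conflicting_types_longest_priority(self):
        out = resolve_annotation_overlaps(
            [Annotation("c", 0, 100, "LTR"), Annotation("c", 50, 200, "LINE")]
        )
        # LINE interval is longer: it wins the shared bases
        assert out == [
            Annotation("c", 0, 50, "LTR"),
            Annotation("c", 50, 200, "LINE"),
        ]

    def test_tie_broken_by_type_order(self):
        out = resolve_annotation_overlaps(
            [Annotation("c", 0, 100, "LTR"), Annotation("c", 50, 150, "LINE")],
            type_order=["LTR", "LINE"],
        )
        assert out == [
            Annotation("c", 0, 100, "LTR"),
            Annotation("c", 100, 150, "LINE"),
        ]

    def test_disjoint_unchanged(self):
        anns = [Annotation("c", 0, 50, "LTR"), Annotation("c", 100, 150, "LINE")]
        assert resolve_annotation_overlaps(anns) == anns

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            resolve_annotation_overlaps([Annotation("c", 10, 10, "TE")])


class TestFormats:
    def test_bed_roundtrip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t200\tLTR\nchr1\t300\t400\tLINE\n")
        assert read_bed(p) == [
            Annotation("chr1", 10, 200, "LTR"),
            Annotation("chr1", 300, 400, "LINE"),
        ]

    def test_repeatmasker_out(self, tmp_path):
        p = tmp_path / "a.out"
        header = (
            "   SW   perc perc perc  query    position in query | repeat\n"
            "score   div. del. ins.  sequence  begin  end (left) | class\n"
            "\n"
        )
        row = " 1000  1.0 0.0 0.0  chr1  101  200  (500)  +  rep1  LTR/Gypsy  1  100  (0)  1\n"
        p.write_text(header + row)
        assert read_repeatmasker_out(p) == [Annotation("chr1", 100, 200, "LTR/Gypsy")]


class TestMsaCleaningConfusion:
    def test_positionwise_hand_count(self):
        counts, metrics = msa_cleaning_confusion(
            msa_from("AAAA"), msa_from("--AA"), msa_from("-AAA")
        )
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 0, 2)
        assert metrics.sensitivity == pytest.approx(0.5)
        assert metrics.precision == pytest.approx(1.0)
        assert metrics.f1 == pytest.approx(2 / 3)

    def test_tool_equals_reference_is_perfect(self):
        orig = msa_from("ACGTACGT", "ACGTACGT")
        ref = msa_from("--GTAC--", "ACGTACGT")
        counts, metrics = msa_cleaning_confusion(orig, ref, ref)
        assert metrics.sensitivity == 1.0 and metrics.precision == 1.0 and metrics.f1 == 1.0

    def test_no_cleaning_has_zero_sensitivity(self):
        orig = msa_from("ACGTACGT")
        ref = msa_from("--GTACGT")
        counts, metrics = msa_cleaning_confusion(orig, ref, orig)
        assert counts.tp == 0 and counts.fn == 2
        assert metrics.sensitivity == 0.0

    def test_original_gap_sites_skipped(self):
        counts, _ = msa_cleaning_confusion(
            msa_from("A--A"), msa_from("----"), msa_from("A--A")
        )
        assert counts.total == 2  # only the two nucleotide sites assessed

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            msa_cleaning_confusion(msa_from("AAAA"), msa_from("AAA"), msa_from("AAAA"))


class TestLibraryBenchmark:
    def test_self_comparison_all_perfect(self, rng):
        lib = [(f"r{i}", random_sequence(1500, rng)) for i in range(3)]
        assert set(library_benchmark(lib, lib).values()) == {"Perfect"}

    def test_two_overlapping_high_identity_halves_are_good(self, rng):
        ref_seq = random_sequence(2000, rng)
        halves = [
            ("h1", mutate_sequence(ref_seq[:1100], 0.02, rng)),
            ("h2", mutate_sequence(ref_seq[900:], 0.02, rng)),
        ]
        assert library_benchmark([("r", ref_seq)], halves)["r"] == "Good"

    def test_low_identity_full_match_is_present(self, rng):
        ref_seq = random_sequence(2000, rng)
        denovo = [("d", mutate_sequence(ref_seq, 0.18, rng))]
        assert library_benchmark([("r", ref_seq)], denovo)["r"] == "Present"

    def test_unrelated_sequence_not_found(self, rng):
        assert (
            library_benchmark(
                [("r", random_sequence(2000, rng))], [("x", random_sequence(2000, rng))]
            )["r"]
            == "Not found"
        )

    def test_empty_library_rejected(self, rng):
        with pytest.raises(ValueError):
            library_benchmark([], [("x", random_sequence(100, rng))])
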