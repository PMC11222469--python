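"""Interval overlap, loop classification vs a brute-force oracle, stats, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depbias.intervals import (
    GenomicInterval,
    Loop,
    LoopSet,
    classify_loops,
    intervals_overlap,
    loop_length_stats,
    peak_set_venn,
    read_bed,
    read_bedpe,
    write_bed,
    write_bedpe,
)
from depbias.simulate import simulate_loops


def loop(chrom, l0, l1, r0, r1, label=None):
    return Loop(GenomicInterval(chrom, l0, l1), GenomicInterval(chrom, r0, r1), label)


class TestOverlap:
    def test_partial_overlap(self):
        assert intervals_overlap(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 250))

    def test_half_open_abutting_do_not_overlap(self):
        assert not intervals_overlap(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300))

    def test_different_chromosomes_never_overlap(self):
        assert not intervals_overlap(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10))

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)


class TestClassify:
    def test_identical_loop_is_shared(self):
        ref = LoopSet("r", [loop("chr1", 0, 10, 100, 110)])
        test = LoopSet("t", [loop("chr1", 0, 10, 100, 110)])
        cls = classify_loops(test, ref)
        assert cls.counts == {"shared": 1, "gained": 0, "control_only": 0}

    def test_anchors_matching_different_reference_loops_is_gained(self):
        # left matches R1's left; right matches only R2's right
        r1 = loop("chr1", 0, 10, 100, 110)
        r2 = loop("chr1", 500, 510, 700, 710)
        test = LoopSet("t", [loop("chr1", 0, 10, 700, 710)])
        cls = classify_loops(test, LoopSet("r", [r1, r2]))
        assert cls.counts["gained"] == 1 and cls.counts["shared"] == 0

    def test_unseen_chromosome_is_gained(self):
        ref = LoopSet("r", [loop("chr1", 0, 10, 100, 110)])
        test = LoopSet("t", [loop("chr9", 0, 10, 100, 110)])
        cls = classify_loops(test, ref)
        assert cls.counts["gained"] == 1
        assert len(cls.control_only) == 1

    def test_slop_rescues_near_miss(self):
        ref = LoopSet("r", [loop("chr1", 0, 10, 100, 110)])
        test = LoopSet("t", [loop("chr1", 12, 22, 100, 110)])
        assert classify_loops(test, ref).counts["shared"] == 0
        assert classify_loops(test, ref, slop=5).counts["shared"] == 1


def brute_force_classify(test, reference):
    """Independent O(n*m) oracle for the dual-anchor shared/gained rule."""
    labels = []
    matched = set()
    for t in test:
        shared = False
        for i, r in enumerate(reference):
            if intervals_overlap(t.left, r.left) and intervals_overlap(t.right, r.right):
                shared = True
                matched.add(i)
        labels.append("shared" if shared else "gained")
    control_only = [i for i in range(len(reference.loops)) if i not in matched]
    return labels, control_only


@st.composite
def random_loop_sets(draw):
    def one_set(n):
        loops = []
        seen = set()
        for _ in range(n):
            chrom = draw(st.sampled_from(["chr1", "chr2"]))
            a = draw(st.integers(0, 300))
            b = draw(st.integers(0, 300))
            w1 = draw(st.integers(1, 30))
            w2 = draw(st.integers(1, 30))
            lo, hi = min(a, b), max(a, b)
            key = (chrom, lo, lo + w1, hi, hi + w2)
            if key in seen:
                continue
            seen.add(key)
            loops.append(loop(chrom, lo, lo + w1, hi, hi + w2))
        return loops

    return (
        LoopSet("t", one_set(draw(st.integers(0, 25)))),
        LoopSet("r", one_set(draw(st.integers(1, 25)))),
    )


class TestClassifyOracle:
    @settings(max_examples=150, deadline=None)
    @given(random_loop_sets())
    def test_matches_brute_force_and_partitions(self, sets):
        test, ref = sets
        cls = classify_loops(test, ref)
        want_labels, want_control = brute_force_classify(test, ref)
        assert [l.label for l in cls.test] == want_labels
        assert len(cls.control_only) == len(want_control)
        assert cls.counts["shared"] + cls.counts["gained"] == len(test)

    def test_classification_is_permutation_invariant(self):
        ref, test, _ = simulate_loops(n_shared=30, n_gained=15, n_control_only=10, seed=4)
        c1 = classify_loops(test, ref).counts
        rng = np.random.default_rng(0)
        shuffled = LoopSet("t", [test.loops[i] for i in rng.permutation(len(test))])
        c2 = classify_loops(shuffled, ref).counts
        assert c1 == c2

    def test_planted_classes_recovered_exactly(self):
        ref, test, truth = simulate_loops(n_shared=100, n_gained=50, n_control_only=25, seed=9)
        cls = classify_loops(test, ref)
        assert cls.counts == {"shared": 100, "gained": 50, "control_only": 25}
        # the first n_shared test loops are the planted shared copies
        assert all(l.label == "shared" for l in cls.test.loops[:100])
        assert all(l.label == "gained" for l in cls.test.loops[100:])


class TestLengthStats:
    def test_median_of_three(self):
        loops = [
            loop("chr1", 0, 10, 100_000, 100_010),
            loop("chr1", 0, 10, 225_000, 225_010),
            loop("chr1", 0, 10, 400_000, 400_010),
        ]
        assert loop_length_stats(LoopSet("s", loops))["median"] == pytest.approx(225_000)

    def test_midpoint_length(self):
        l = loop("chr1", 100, 200, 900, 1000)
        assert l.length("midpoint") == pytest.approx(800)  # 950 - 150
        assert l.length("start") == pytest.approx(800)

    def test_even_n_median_is_mean_of_middle_two(self):
        loops = [loop("chr1", 0, 10, 100, 110), loop("chr1", 0, 10, 300, 310)]
        assert loop_length_stats(LoopSet("s", loops))["median"] == pytest.approx(200)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            loop_length_stats(LoopSet("s", []))


class TestPeakVenn:
    def test_directional_counts(self):
        a = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        b = [GenomicInterval("chr1", 5, 8), GenomicInterval("chr1", 100, 110)]
        v = peak_set_venn(a, b)
        assert (v.a_with_overlap, v.a_only, v.b_with_overlap, v.b_only) == (1, 1, 1, 1)

    def test_identical_sets(self):
        a = [GenomicInterval("chr1", 0, 10)]
        v = peak_set_venn(a, list(a))
        assert v.a_only == 0 and v.b_only == 0

    def test_disjoint_sets(self):
        v = peak_set_venn([GenomicInterval("chr1", 0, 10)], [GenomicInterval("chr1", 50, 60)])
        assert v.a_with_overlap == 0 and v.b_with_overlap == 0

    def test_multi_overlap_directions_differ(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 30, 40)]
        v = peak_set_venn(a, b)
        assert v.a_with_overlap == 1 and v.b_with_overlap == 2


class TestIO:
    def test_bed_round_trip_skips_track_lines(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("track name=peaks\nchr1\t0\t100\nchr2\t50\t60\n")
        ivs = read_bed(p)
        assert len(ivs) == 2 and ivs[1] == GenomicInterval("chr2", 50, 60)
        q = tmp_path / "y.bed"
        write_bed(ivs, q)
        assert read_bed(q) == ivs

    def test_bed_short_line_reports_lineno(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t100\nchr1\t5\n")
        with pytest.raises(ValueError, match=":2:"):
            read_bed(p)

    def test_bedpe_trans_loop_rejected(self, tmp_path):
        p = tmp_path / "x.bedpe"
        p.write_text("chr1\t0\t10\tchr2\t100\t110\n")
        with pytest.raises(ValueError, match="chromosome"):
            read_bedpe(p)

    def test_simulated_bedpe_round_trips_bytewise(self, tmp_path):
        ref, test, _ = simulate_loops(n_shared=300, n_gained=200, n_control_only=200, seed=12)
        p1, p2 = tmp_path / "a.bedpe", tmp_path / "b.bedpe"
        write_bedpe(test, p1)
        write_bedpe(read_bedpe(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
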