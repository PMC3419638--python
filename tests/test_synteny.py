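import itertools

import numpy as np
import pytest

from bespipe.io_formats import AlignmentHit
from bespipe.synteny import (aligned_bes_total, classify_library,
                             classify_pair, no_hit_bes_total,
                             pair_orientation, select_best_placement)


def hit(chrom, start, end, strand, score=500.0, read="r"):
    return AlignmentHit(read, 0, int(score), chrom, start, end, strand,
                        score, 1e-50)


class TestPairOrientation:
    def test_opposite_in(self):
        u = hit("chr1", 100_000, 101_000, "+")
        d = hit("chr1", 220_000, 221_000, "-")
        assert pair_orientation(u, d) == "opposite_in"
        assert pair_orientation(d, u) == "opposite_in"

    def test_same(self):
        assert pair_orientation(hit("chr1", 0, 1000, "+"),
                                hit("chr1", 50_000, 51_000, "+")) == "same"
        assert pair_orientation(hit("chr1", 0, 1000, "-"),
                                hit("chr1", 50_000, 51_000, "-")) == "same"

    def test_opposite_out(self):
        assert pair_orientation(hit("chr1", 0, 1000, "-"),
                                hit("chr1", 50_000, 51_000, "+")) == "opposite_out"

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError):
            pair_orientation(hit("chr1", 0, 1000, "+"), hit("chr2", 0, 1000, "-"))


class TestClassifyPair:
    @pytest.mark.parametrize("up_strand,down_strand,span,label", [
        ("+", "-", 150_000, "C1"),   # opposite-in, in window: concordant
        ("+", "+", 150_000, "C2"),
        ("+", "-", 400_000, "C3"),
        ("-", "-", 400_000, "C4"),
        ("-", "+", 400_000, "C5"),
        ("+", "-", 10_000, "X1"),
        ("+", "+", 10_000, "X2"),
        ("-", "+", 10_000, "X3"),
        ("-", "+", 150_000, "X4"),
        ("+", "-", 20_000, "C1"),    # window boundaries are inclusive
        ("+", "-", 300_000, "C1"),
        ("+", "-", 300_001, "C3"),
        ("+", "-", 19_999, "X1"),
    ])
    def test_orientation_span_grid(self, up_strand, down_strand, span, label):
        f = [hit("chr2", 100_000, 101_000, up_strand)]
        r = [hit("chr2", 100_000 + span - 1_000, 100_000 + span, down_strand)]
        call = classify_pair("b", f, r)
        assert call.class_label == label
        assert call.concordant == (label == "C1")

    def test_different_chromosomes_is_c6(self):
        call = classify_pair("b", [hit("chr1", 0, 1000, "+")],
                             [hit("chr2", 0, 1000, "-")])
        assert call.class_label == "C6"

    def test_single_end_single_hit_is_c7(self):
        assert classify_pair("b", [hit("chr1", 0, 1000, "+")], []).class_label == "C7"

    def test_single_end_multiple_hits_is_c8(self):
        hits = [hit("chr1", i * 50_000, i * 50_000 + 1000, "+") for i in range(3)]
        assert classify_pair("b", [], hits).class_label == "C8"

    def test_no_hits_is_c9(self):
        assert classify_pair("b", [], []).class_label == "C9"

    def test_same_chromosome_pairing_beats_cross_chromosome_score(self):
        f = [hit("chr1", 100_000, 101_000, "+", 300), hit("chr3", 0, 1000, "+", 900)]
        r = [hit("chr1", 250_000, 251_000, "-", 300), hit("chr4", 0, 1000, "-", 900)]
        assert classify_pair("b", f, r).class_label == "C1"
        assert classify_pair("b", f, r,
                             allow_cross_chrom_override=True).class_label == "C6"

    def test_window_widening_never_evicts_c1(self):
        f = [hit("chr1", 0, 1000, "+")]
        r = [hit("chr1", 149_000, 150_000, "-")]
        assert classify_pair("b", f, r).class_label == "C1"
        assert classify_pair("b", f, r, min_span=10_000,
                             max_span=500_000).class_label == "C1"


class TestSelectBestPlacement:
    def test_single_candidate(self):
        f, r = [hit("chr1", 0, 1000, "+")], [hit("chr1", 90_000, 91_000, "-")]
        p = select_best_placement("b", f, r)
        assert (p.hit_f, p.hit_r) == (f[0], r[0])

    def test_matches_exhaustive_argmax_on_3x3(self, rng):
        """Best-score-sum selection equals brute-force enumeration."""
        for trial in range(50):
            chroms = ["chr1", "chr2"]
            f = [hit(chroms[int(rng.integers(2))], int(s := rng.integers(0, 500_000)),
                     int(s) + 1000, "+", float(rng.integers(100, 999)))
                 for _ in range(3)]
            r = [hit(chroms[int(rng.integers(2))], int(s := rng.integers(0, 500_000)),
                     int(s) + 1000, "-", float(rng.integers(100, 999)))
                 for _ in range(3)]
            p = select_best_placement("b", f, r)
            same = [(a, b) for a, b in itertools.product(f, r) if a.chrom == b.chrom]
            if not same:
                assert p is None
            else:
                assert p.score_sum == max(a.score + b.score for a, b in same)

    def test_tie_prefers_concordant(self):
        f = [hit("chr1", 0, 1000, "+", 500)]
        r = [hit("chr1", 99_000, 100_000, "-", 500),    # concordant pairing
             hit("chr1", 350_000, 351_000, "-", 500)]   # same score, long span
        p = select_best_placement("b", f, r)
        assert p.span == 100_000

    def test_no_shared_chromosome_returns_none(self):
        assert select_best_placement(
            "b", [hit("chr1", 0, 1000, "+")], [hit("chr2", 0, 1000, "-")]) is None


class TestClassifyLibrary:
    def test_partition_and_symmetry(self, rng):
        """Class counts partition the clones; swapping the forward/reverse
        roles of every clone's ends changes no label."""
        clones = {}
        for i in range(40):
            n_f, n_r = int(rng.integers(0, 3)), int(rng.integers(0, 3))
            mk = lambda n, strand: [hit(f"chr{int(rng.integers(1, 4))}",
                                        int(s := rng.integers(0, 400_000)),
                                        int(s) + 1000, strand,
                                        float(rng.integers(100, 999)))
                                    for _ in range(n)]
            clones[f"b{i}"] = {"f": mk(n_f, "+"), "r": mk(n_r, "-")}
        calls, counts = classify_library(clones)
        assert sum(counts.values()) == 40
        swapped = {c: {"f": ends["r"], "r": ends["f"]} for c, ends in clones.items()}
        calls2, counts2 = classify_library(swapped)
        assert [c.class_label for c in calls] == [c.class_label for c in calls2]

    def test_extra_end_key_rejected(self):
        with pytest.raises(ValueError):
            classify_library({"b": {"f": [], "r": [], "x": []}})

    def test_published_count_identities(self):
        """The printed per-class clone counts imply 265 aligned end
        sequences and 192 clones; the accounting must reproduce both."""
        counts = dict(zip(
            ["C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9"],
            [42, 1, 16, 12, 15, 9, 10, 65, 22]))
        assert sum(counts.values()) == 192
        assert aligned_bes_total(counts) == 265
        assert no_hit_bes_total(counts) == 2 * 22 + 10 + 65
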