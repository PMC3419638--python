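import numpy as np
import pytest

from bespipe.io_formats import RepeatAnnotationRecord, SeqRecord, revcomp
from bespipe.mapping import (SeedIndex, annotate_repeats, brute_force_map,
                             map_read, repeat_fraction)
from bespipe.repeat_summary import RepeatTaxonomy
from bespipe.synthetic import mutate, random_sequence

from conftest import make_read


class TestMapRead:
    def test_exact_substring_maps_to_true_position(self, small_genome, small_index):
        read = make_read("r", small_genome, "chr3", 50_000, 800)
        hits = map_read(read, small_index)
        top = hits[0]
        assert (top.chrom, top.ref_start, top.ref_end, top.strand) == \
            ("chr3", 50_000, 50_800, "+")

    def test_reverse_complement_read_maps_minus_strand(self, small_genome, small_index):
        read = make_read("r", small_genome, "chr2", 10_000, 600, strand="-")
        top = map_read(read, small_index)[0]
        assert (top.chrom, top.ref_start, top.ref_end, top.strand) == \
            ("chr2", 10_000, 10_600, "-")

    def test_random_read_finds_nothing(self, small_index, rng):
        read = SeqRecord("r", random_sequence(rng, 700, 0.44))
        assert map_read(read, small_index) == []

    def test_read_shorter_than_k_is_empty(self, small_index):
        assert map_read(SeqRecord("r", "ACGTACGTAC"), small_index) == []

    def test_tolerates_substitution_errors(self, small_genome, small_index, rng):
        seq = small_genome["chr1"][30_000:30_900]
        read = SeqRecord("r", mutate(rng, seq, 0.01))
        top = map_read(read, small_index)[0]
        assert top.chrom == "chr1"
        assert abs(top.ref_start - 30_000) < 50 and abs(top.ref_end - 30_900) < 50

    def test_strand_antisymmetry(self, small_genome, small_index, rng):
        """Mapping the reverse complement flips every strand, same intervals."""
        for i in range(10):
            read = make_read(f"r{i}", small_genome, "chr4",
                             int(rng.integers(0, 190_000)), 700)
            fwd = map_read(read, small_index)
            rev = map_read(SeqRecord(read.id, revcomp(read.sequence)), small_index)
            assert {(h.chrom, h.ref_start, h.ref_end, h.strand) for h in fwd} == \
                {(h.chrom, h.ref_start, h.ref_end,
                  "+" if h.strand == "-" else "-") for h in rev}

    def test_evalue_monotonicity(self, small_genome, small_index, rng):
        """Raising the E-value ceiling never removes hits."""
        read = make_read("r", small_genome, "chr5", 120_000, 500)
        loose = {(h.chrom, h.ref_start) for h in
                 map_read(read, small_index, max_evalue=1e-5)}
        strict = {(h.chrom, h.ref_start) for h in
                  map_read(read, small_index, max_evalue=1e-40)}
        assert strict <= loose


class TestOracleEquivalence:
    def test_error_free_reads_match_brute_force(self, small_genome, small_index, rng):
        """The seeded mapper and the exhaustive scan agree hit-for-hit."""
        for i in range(50):
            chrom = f"chr{int(rng.integers(1, 6))}"
            L = int(rng.integers(400, 1000))
            start = int(rng.integers(0, 200_000 - L))
            strand = "+" if rng.random() < 0.5 else "-"
            read = make_read(f"r{i}", small_genome, chrom, start, L, strand)
            seeded = {(h.chrom, h.ref_start, h.ref_end, h.strand)
                      for h in map_read(read, small_index)}
            exact = {(h.chrom, h.ref_start, h.ref_end, h.strand)
                     for h in brute_force_map(read, small_genome, 0)}
            assert seeded == exact

    def test_brute_force_mismatch_path(self, rng):
        genome = {"c": random_sequence(rng, 5_000, 0.5)}
        seq = mutate(rng, genome["c"][1000:1200], 0.01)
        hits = brute_force_map(SeqRecord("r", seq), genome, max_mismatch=5)
        assert any(h.ref_start == 1000 and h.strand == "+" for h in hits)

    def test_empty_genome(self):
        assert brute_force_map(SeqRecord("r", "ACGT" * 30), {}, 0) == []

    def test_read_equal_to_whole_chromosome(self, rng):
        genome = {"c": random_sequence(rng, 2_000, 0.5)}
        hits = brute_force_map(SeqRecord("r", genome["c"]), genome, 0)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1 and (plus[0].ref_start, plus[0].ref_end) == (0, 2000)


@pytest.fixture(scope="module")
def taxonomy():
    return RepeatTaxonomy.default()


@pytest.fixture(scope="module")
def library():
    g = np.random.default_rng(7)
    return {
        "Copia": SeqRecord("Copia", random_sequence(g, 3000, 0.44)),
        "Gypsy": SeqRecord("Gypsy", random_sequence(g, 3000, 0.44)),
        "hAT": SeqRecord("hAT", random_sequence(g, 1200, 0.44)),
    }


class TestAnnotateRepeats:
    def test_planted_full_copy_recovered(self, library, taxonomy, rng):
        flank = random_sequence(rng, 300, 0.44)
        copy = library["Copia"].sequence[:400]
        read = SeqRecord("r", flank + copy + flank[::-1])
        anns = annotate_repeats(read, list(library.values()), taxonomy)
        assert len(anns) == 1
        a = anns[0]
        assert a.family == "Copia"
        assert a.lineage == ("Transposable Element", "RNA transposon",
                             "LTR Retrotransposon", "Copia")
        assert abs(a.start - 300) <= 10 and abs(a.end - 700) <= 10

    def test_clean_read_has_no_annotations(self, library, taxonomy, rng):
        read = SeqRecord("r", random_sequence(rng, 800, 0.44))
        assert annotate_repeats(read, list(library.values()), taxonomy) == []

    def test_two_planted_repeats_disjoint(self, library, taxonomy, rng):
        gap = random_sequence(rng, 200, 0.44)
        read = SeqRecord("r", gap + library["Copia"].sequence[:300] + gap
                         + library["hAT"].sequence[:300] + gap)
        anns = annotate_repeats(read, list(library.values()), taxonomy)
        assert sorted(a.family for a in anns) == ["Copia", "hAT"]
        a, b = sorted(anns, key=lambda x: x.start)
        assert a.end <= b.start

    def test_diverged_copy_still_found(self, library, taxonomy, rng):
        copy = mutate(rng, library["Gypsy"].sequence[:600], 0.10)
        read = SeqRecord("r", random_sequence(rng, 200, 0.44) + copy)
        anns = annotate_repeats(read, list(library.values()), taxonomy)
        assert any(a.family == "Gypsy" for a in anns)

    def test_annotations_never_overlap(self, library, taxonomy, rng):
        # two families sharing sequence force a cross-family conflict
        shared = library["Copia"].sequence[:500]
        fake_gypsy = SeqRecord("Gypsy", shared[100:450])
        read = SeqRecord("r", shared + random_sequence(rng, 100, 0.44))
        anns = annotate_repeats(read, [library["Copia"], fake_gypsy], taxonomy)
        anns = sorted(anns, key=lambda a: a.start)
        for a, b in zip(anns, anns[1:]):
            assert a.end <= b.start
        # the longer, higher-scoring Copia match wins the contested interval
        assert anns[0].family == "Copia"


class TestRepeatFraction:
    def _ann(self, s, e):
        return RepeatAnnotationRecord("r", s, e, "Copia")

    def test_no_annotations_is_zero(self):
        assert repeat_fraction(SeqRecord("r", "A" * 300), []) == 0.0

    def test_full_cover_is_one(self):
        read = SeqRecord("r", "A" * 200)
        assert repeat_fraction(read, [self._ann(0, 200)]) == 1.0

    def test_overlapping_intervals_union(self):
        read = SeqRecord("r", "A" * 300)
        assert repeat_fraction(read, [self._ann(0, 100), self._ann(50, 150)]) == 0.5
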