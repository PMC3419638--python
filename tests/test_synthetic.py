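import numpy as np
import pytest

from bespipe.io_formats import Config, revcomp
from bespipe.synthetic import (BACClone, Block, RearrangementPlan,
                               derive_reference_genome, extract_bes,
                               generate_query_genome, generate_repeat_library,
                               inject_contamination, make_plan,
                               random_sequence, sample_bac_clones)

GC = 0.44


class TestQueryGenome:
    def test_gc_concentration(self):
        genome, _ = generate_query_genome(1, 1_000_000, 0.5, None, 0.0,
                                          seed=1, max_insert=50_000)
        seq = genome["chr01"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_zero_density_plants_nothing(self):
        _, planted = generate_query_genome(1, 500_000, GC, None, 0.0,
                                           seed=2, max_insert=40_000)
        assert planted == []

    def test_same_seed_identical(self):
        lib = generate_repeat_library(3)
        g1, p1 = generate_query_genome(2, 300_000, GC, lib, 0.3, seed=3,
                                       max_insert=20_000)
        g2, p2 = generate_query_genome(2, 300_000, GC, lib, 0.3, seed=3,
                                       max_insert=20_000)
        assert g1 == g2 and p1 == p2

    def test_excessive_density_rejected(self):
        lib = generate_repeat_library(1)
        with pytest.raises(ValueError):
            generate_query_genome(1, 300_000, GC, lib, 0.95, seed=1,
                                  max_insert=20_000)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            generate_query_genome(1, 100_000, GC, None, 0.0, seed=1,
                                  max_insert=50_000)

    def test_planted_density_near_target(self):
        lib = generate_repeat_library(5)
        genome, planted = generate_query_genome(1, 2_000_000, GC, lib, 0.4,
                                                seed=5, max_insert=50_000)
        covered = sum(p.end - p.start for p in planted)
        assert abs(covered / 2_000_000 - 0.4) < 0.08


class TestReferenceDerivation:
    def _genome(self, seed=11, n=1, length=400_000):
        g, _ = generate_query_genome(n, length, GC, None, 0.0, seed=seed,
                                     max_insert=30_000)
        return g

    def test_identity_plan_reproduces_query(self):
        query = self._genome()
        plan = RearrangementPlan([Block("chr01", 0, 400_000, "chr01", 1.0, False)])
        ref = derive_reference_genome(query, plan, seed=1)
        assert ref == query

    def test_single_block_scale_forces_length(self):
        query = {"chr01": random_sequence(np.random.default_rng(0), 100_000, GC)}
        plan = RearrangementPlan([Block("chr01", 0, 100_000, "chr01", 1.3, False)])
        ref = derive_reference_genome(query, plan, seed=2)
        assert len(ref["chr01"]) == 130_000

    def test_inverted_identity_block_is_revcomp(self):
        query = self._genome()
        plan = RearrangementPlan([Block("chr01", 0, 400_000, "chr01", 1.0, True)])
        ref = derive_reference_genome(query, plan, seed=3)
        assert ref["chr01"] == revcomp(query["chr01"])

    def test_mean_scale_realized_over_many_blocks(self):
        query = self._genome(seed=13, n=2, length=12_000_000)
        plan = make_plan(query, seed=13, block_length=400_000,
                         mean_expansion=1.3, expansion_sd=0.15)
        assert len(plan.blocks) >= 50
        ref = derive_reference_genome(query, plan, seed=13)
        ratio = sum(map(len, ref.values())) / sum(map(len, query.values()))
        assert abs(ratio - 1.3) < 0.05

    def test_plan_tiles_whole_genome(self):
        query = self._genome(seed=17, n=3, length=1_200_000)
        plan = make_plan(query, seed=17)
        assert sum(b.query_end - b.query_start for b in plan.blocks) == \
            sum(map(len, query.values()))

    def test_non_tiling_plan_rejected(self):
        query = self._genome()
        plan = RearrangementPlan([Block("chr01", 100, 400_000, "chr01", 1.0, False)])
        with pytest.raises(ValueError):
            derive_reference_genome(query, plan, seed=1)


@pytest.fixture(scope="module")
def genome():
    g, _ = generate_query_genome(2, 3_000_000, GC, None, 0.0, seed=23)
    return g


@pytest.fixture(scope="module")
def insert():
    return random_sequence(np.random.default_rng(37), 10_000, GC)


class TestClones:
    def test_empty_and_negative(self, genome):
        assert sample_bac_clones(genome, 0, seed=1) == []
        with pytest.raises(ValueError):
            sample_bac_clones(genome, -1, seed=1)

    def test_insert_size_distribution(self, genome):
        clones = sample_bac_clones(genome, 1000, seed=29)
        sizes = np.array([c.insert_size for c in clones])
        assert abs(sizes.mean() - 125_000) < 4_000
        assert sizes.min() >= 29_000 and sizes.max() <= 293_000
        # the size model is calibrated so ~88% of inserts exceed 90 kb
        assert abs((sizes > 90_000).mean() - 0.88) < 0.05

    def test_clones_fit_their_chromosome(self, genome):
        for c in sample_bac_clones(genome, 200, seed=31):
            assert 0 <= c.origin_start < c.origin_end <= len(genome[c.origin_chrom])
            assert c.origin_end - c.origin_start == c.insert_size


class TestBESExtraction:
    def _clone(self, size=10_000):
        return BACClone("b1", size, "chr01", 0, size)

    def test_error_free_reads_are_exact_substrings(self, insert):
        fwd, rev = extract_bes(self._clone(), insert, seed=41, error_rate=0.0)
        assert insert.startswith(fwd.sequence)
        assert insert.endswith(revcomp(rev.sequence))
        assert fwd.id == "b1.f" and rev.id == "b1.r"

    def test_length_distribution(self, insert):
        lengths = []
        for i in range(378):
            f, r = extract_bes(self._clone(), insert, seed=1000 + i, error_rate=0.0)
            lengths.extend([len(f), len(r)])
        lengths = np.array(lengths[:756])
        assert abs(lengths.mean() - 944) < 15
        assert lengths.min() >= 312

    def test_insert_too_short_rejected(self):
        with pytest.raises(ValueError):
            extract_bes(BACClone("b", 400, "c", 0, 400), "A" * 400, seed=1)

    def test_quality_decays_toward_three_prime(self, insert):
        fwd, _ = extract_bes(self._clone(), insert, seed=43)
        assert fwd.quality[0] > fwd.quality[-1]


class TestContamination:
    def _clones(self, n):
        return [BACClone(f"b{i}", 100_000, "chr01", 0, 100_000) for i in range(n)]

    def test_rate_zero_and_one(self):
        clones = self._clones(20)
        assert inject_contamination(clones, 150_000, 0.0, seed=1) == clones
        assert all(c.contaminated for c in
                   inject_contamination(clones, 150_000, 1.0, seed=1))

    def test_binomial_mean_at_library_rate(self):
        """0.5% of 192 clones -> 0.96 expected contaminated clones; the
        replicate mean converges to the binomial expectation."""
        clones = self._clones(192)
        counts = [sum(c.contaminated for c in
                      inject_contamination(clones, 150_000, 0.005, seed=s))
                  for s in range(1000)]
        assert abs(np.mean(counts) - 0.96) < 0.1
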