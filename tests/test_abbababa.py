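"""Base sampling, site classification, block accumulation and the
weighted jackknife, including the published worked examples."""

import numpy as np
import pytest

from conftest import classical_delete1_jackknife
from glpop.abbababa import (ABBA, BABA, NEITHER, BlockCounts,
                            accumulate_blocks, all_triples, classify_site,
                            dstat_from_counts, dstat_jackknife, sample_base)
from glpop.simulate import sim_quartet


class TestSampleBase:
    def test_single_passing_read(self, rng):
        assert sample_base([("A", 30)], 20, rng) == "A"

    def test_no_passing_reads_is_none(self, rng):
        assert sample_base([("A", 10)], 20, rng) is None
        assert sample_base([], 20, rng) is None

    def test_sampling_is_uniform_over_reads(self, rng):
        reads = [("A", 30)] * 3 + [("G", 30)]
        draws = sum(sample_base(reads, 0, rng) == "G" for _ in range(10_000))
        assert draws / 10_000 == pytest.approx(0.25, abs=0.02)


class TestClassify:
    @pytest.mark.parametrize("b1,b2,b3,anc,expect", [
        ("A", "G", "G", "A", ABBA),
        ("G", "A", "G", "A", BABA),
        ("A", "C", "G", "A", NEITHER),   # triallelic
        ("A", "A", "A", "A", NEITHER),   # no derived allele
        ("C", "C", "C", "A", NEITHER),   # concordant derived
    ])
    def test_patterns(self, b1, b2, b3, anc, expect):
        assert classify_site(b1, b2, b3, anc) == expect

    def test_rm_trans_drops_transitions_only(self):
        assert classify_site("A", "G", "G", "A", rm_trans=True) == NEITHER
        assert classify_site("T", "C", "C", "T", rm_trans=True) == NEITHER
        assert classify_site("A", "C", "C", "A", rm_trans=True) == ABBA


class TestBlocks:
    def test_boundary_placement(self):
        classified = [("chr1", 100, ABBA), ("chr1", 100, BABA),
                      ("chr1", 101, ABBA)]
        blocks = accumulate_blocks(classified, block_size=100)
        assert [(b.block_index, b.n_abba, b.n_baba) for b in blocks] == \
            [(0, 1, 1), (1, 1, 0)]

    def test_neither_and_empty_blocks_dropped(self):
        blocks = accumulate_blocks([("chr1", 5, NEITHER)], block_size=10)
        assert blocks == []

    def test_chromosomes_kept_apart(self):
        classified = [("chr1", 5, ABBA), ("chr2", 5, BABA)]
        blocks = accumulate_blocks(classified, block_size=10)
        assert {(b.chrom, b.block_index) for b in blocks} == \
            {("chr1", 0), ("chr2", 0)}


class TestDstat:
    # Published worked examples: pooled counts -> D at two decimals
    @pytest.mark.parametrize("n_abba,n_baba,expect", [
        (355539, 360029, -0.01),
        (361594, 369006, -0.01),
        (653515, 360029, 0.29),
        (711281, 334990, 0.36),
        (103016, 90667, 0.06),
        (286551, 90667, 0.52),
        (286551, 103016, 0.47),
    ])
    def test_worked_examples(self, n_abba, n_baba, expect):
        assert round(dstat_from_counts(n_abba, n_baba), 2) == expect

    def test_zero_counts_is_error(self):
        with pytest.raises(ValueError):
            dstat_from_counts(0, 0)

    def test_equal_blocks_reduce_to_classical_jackknife(self, rng):
        # equal-weight blocks: same total count in every block
        per_block = []
        for _ in range(12):
            a = int(rng.integers(20, 80))
            per_block.append((a, 100 - a))
        blocks = [BlockCounts("chr1", i, a, b)
                  for i, (a, b) in enumerate(per_block)]
        res = dstat_jackknife(blocks)
        est, se = classical_delete1_jackknife(per_block)
        assert res.jack_est == pytest.approx(est, abs=1e-12)
        assert res.se == pytest.approx(se, abs=1e-12)

    def test_needs_two_informative_blocks(self):
        with pytest.raises(ValueError):
            dstat_jackknife([BlockCounts("chr1", 0, 5, 3)])


class TestAllTriples:
    @staticmethod
    def _simple_dataset(rng, n_ind=3, n_sites=600):
        bases = np.array(list("ACGT"))[rng.integers(0, 4, size=(n_sites, n_ind))]
        anc = np.array(list("ACGT"))[rng.integers(0, 4, size=n_sites)]
        chroms = ["chr1"] * n_sites
        positions = np.arange(1, n_sites + 1) * 50
        return bases.astype(object), anc.astype(object), chroms, positions

    def test_three_individuals_give_six_rows(self, rng):
        bases, anc, chroms, pos = self._simple_dataset(rng)
        res = all_triples(bases, anc, chroms, pos, ["a", "b", "c"],
                          block_size=5000)
        assert len(res) == 6

    def test_five_individuals_full_and_reduced_counts(self, rng):
        bases, anc, chroms, pos = self._simple_dataset(rng, n_ind=5)
        names = list("abcde")
        full = all_triples(bases, anc, chroms, pos, names, block_size=5000)
        reduced = all_triples(bases, anc, chroms, pos, names, block_size=5000,
                              reduced=True)
        assert len(full) == 60 and len(reduced) == 30

    def test_swapping_h1_h2_flips_sign(self, rng):
        bases, anc, chroms, pos = self._simple_dataset(rng)
        res = all_triples(bases, anc, chroms, pos, ["a", "b", "c"],
                          block_size=5000)
        table = {(r.h1, r.h2, r.h3): r for r in res}
        fwd, rev = table[("a", "b", "c")], table[("b", "a", "c")]
        assert fwd.d == pytest.approx(-rev.d, abs=1e-12)
        assert fwd.n_abba == rev.n_baba


class TestSimulatedD:
    def test_null_quartet_rarely_exceeds_3_se(self):
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            truth = sim_quartet(5000, p_abba=0.05, p_baba=0.05, seed=rep)
            classified = [
                (truth.chroms[s], int(truth.positions[s]),
                 classify_site(truth.bases[s, 0], truth.bases[s, 1],
                               truth.bases[s, 2], truth.anc[s]))
                for s in range(5000)]
            blocks = accumulate_blocks(classified, block_size=100_000)
            res = dstat_jackknife(blocks)
            hits += abs(res.z) < 3
        assert hits / n_rep >= 0.95

    def test_introgression_shifts_d_positive(self):
        truth = sim_quartet(100_000, p_abba=0.06, p_baba=0.04, seed=1)
        classified = [
            (truth.chroms[s], int(truth.positions[s]),
             classify_site(truth.bases[s, 0], truth.bases[s, 1],
                           truth.bases[s, 2], truth.anc[s]))
            for s in range(100_000)]
        blocks = accumulate_blocks(classified, block_size=1_000_000)
        res = dstat_jackknife(blocks)
        assert res.d == pytest.approx(truth.expected_d, abs=0.03)
        assert res.z > 3
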