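"""Window counting, binomial p-values, BH, strand separation, region calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from chiptarget.config import PipelineConfig, SimulationParams
from chiptarget.peaks import (call_regions, intersect_replicates,
                              strand_separation_test, tile_counts, window_pvalues,
                              window_table)
from chiptarget.simulate import simulate_chip_reads, simulate_genome, simulate_input_reads
from chiptarget.stats import benjamini_hochberg
from chiptarget.types import AlignedRead, BindingRegion, ReadSet


def brute_force_bh(p):
    """Direct step-up evaluation: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for rank, i in enumerate(order, start=1):
        q[i] = min(min(p[order[j - 1]] * n / j for j in range(rank, n + 1)), 1.0)
    return q


class TestTileCounts:
    def test_no_reads_all_zero(self):
        tiles = tile_counts(ReadSet.empty(), {"chr1": 1000}, 100)
        assert tiles["chr1"].sum() == 0
        assert len(tiles["chr1"]) == 10

    def test_read_at_150_lands_in_tile_1(self):
        reads = ReadSet.from_reads([AlignedRead("chr1", 150, 100, "+")])
        tiles = tile_counts(reads, {"chr1": 1000}, 100)
        assert tiles["chr1"][1] == 1
        assert tiles["chr1"].sum() == 1

    def test_minus_read_assigned_by_five_prime(self):
        # read [100, 200) on minus strand: 5' = 199 -> tile 1
        reads = ReadSet.from_reads([AlignedRead("chr1", 100, 100, "-")])
        tiles = tile_counts(reads, {"chr1": 1000}, 100)
        assert tiles["chr1"][1] == 1

    def test_counts_conserved(self, rng):
        starts = rng.integers(0, 900, size=1000)
        reads = ReadSet(["chr1"] * 1000, starts, np.full(1000, 100), np.zeros(1000, bool))
        tiles = tile_counts(reads, {"chr1": 1000}, 100)
        assert tiles["chr1"].sum() == 1000

    def test_out_of_bounds_read_rejected(self):
        reads = ReadSet.from_reads([AlignedRead("chr1", 2000, 100, "+")])
        with pytest.raises(ValueError, match="outside"):
            tile_counts(reads, {"chr1": 1000}, 100)


class TestWindowPvalues:
    def _table(self, chip, inp):
        return window_table({"chr1": np.array(chip)}, {"chr1": np.array(inp)})

    def test_zero_count_gives_p_one(self):
        df = window_pvalues(self._table([0, 5], [0, 5]), 1000, 1000, 100_000, 100)
        assert df.loc[0, "p_peak"] == 1.0
        assert df.loc[0, "p_input"] == 1.0

    def test_balanced_split_is_null_mode(self):
        df = window_pvalues(self._table([7], [7]), 1000, 1000, 100_000, 100)
        assert df.loc[0, "p_input"] >= 0.5

    def test_input_pvalue_exact_binomial_tail(self):
        # chip=10, input=0 (+1 pseudocount), equal totals:
        # upper tail of Binomial(11, 1/2) at 10 = (11 + 1) / 2^11
        df = window_pvalues(self._table([10], [0]), 1000, 1000, 100_000, 100)
        assert df.loc[0, "p_input"] == pytest.approx(12 / 2048, rel=1e-12)

    def test_p_peak_is_uniform_background_tail(self):
        df = window_pvalues(self._table([3], [0]), 500, 500, 50_000, 100)
        expected = sps.binom.sf(2, 500, 100 / 50_000)
        assert df.loc[0, "p_peak"] == pytest.approx(expected, rel=1e-12)

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            window_pvalues(self._table([1], [1]), 10, 10, 0, 100)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_evaluated_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_unchanged(self):
        q = benjamini_hochberg([0.2, 0.2, 0.2])
        assert q == pytest.approx([0.2, 0.2, 0.2])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    def test_equals_brute_force_step_up(self, pvals):
        q = benjamini_hochberg(pvals)
        assert np.allclose(q, brute_force_bh(pvals), atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.random(100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestStrandSeparation:
    def test_maximal_separation_gives_minimal_p(self, rng):
        plus = np.arange(0, 50)
        minus = np.arange(200, 250)
        _, p = strand_separation_test(plus, minus, rng, n_permutations=999)
        assert p <= 1 / (999 + 1) + 1e-12

    def test_single_strand_gives_p_one(self, rng):
        _, p = strand_separation_test(np.array([1.0, 2.0]), np.array([]), rng)
        assert p == 1.0

    def test_statistic_is_mean_difference(self, rng):
        sep, _ = strand_separation_test(np.array([0.0, 10.0]), np.array([100.0, 110.0]), rng)
        assert sep == pytest.approx(100.0)


class TestCallRegions:
    def _run(self, chip_counts, reads, config=None):
        cfg = config or PipelineConfig()
        table = window_table({"chr1": np.array(chip_counts)},
                             {"chr1": np.zeros(len(chip_counts), dtype=int)})
        table = window_pvalues(table, 10_000, 10_000, 1_000_000, cfg.window_size)
        return call_regions(table, reads, cfg, seed=5)

    def test_no_significant_windows_empty(self):
        counts = np.ones(50, dtype=int)
        assert self._run(counts, ReadSet.empty()) == []

    def test_adjacent_tiles_merge_into_one_region(self, rng):
        counts = np.zeros(100, dtype=int)
        counts[10] = counts[11] = 60
        # plus reads left, minus reads right: correct orientation
        plus = rng.integers(1000, 1100, 60)
        minus = rng.integers(1100, 1200, 60)
        reads = ReadSet(["chr1"] * 120, np.concatenate([plus, minus - 99]),
                        np.full(120, 100), np.r_[np.zeros(60, bool), np.ones(60, bool)])
        regions = self._run(counts, reads)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1000, 1200)

    def test_wrong_orientation_screened_out(self, rng):
        counts = np.zeros(100, dtype=int)
        counts[10] = counts[11] = 60
        # minus reads left of plus reads: anti-correlated with binding
        minus = rng.integers(1000, 1100, 60)
        plus = rng.integers(1100, 1200, 60)
        reads = ReadSet(["chr1"] * 120, np.concatenate([plus, minus - 99]),
                        np.full(120, 100), np.r_[np.zeros(60, bool), np.ones(60, bool)])
        assert self._run(counts, reads) == []


class TestIntersectReplicates:
    def _region(self, start, end, chrom="chr1"):
        return BindingRegion(chrom=chrom, start=start, end=end, condition="c",
                             q_peak=1e-5, q_input=1e-3, strand_sep_q=0.01)

    def test_identical_lists_idempotent(self):
        regions = [self._region(100, 300), self._region(500, 700)]
        out = intersect_replicates(regions, regions)
        assert [(r.start, r.end) for r in out] == [(100, 300), (500, 700)]
        assert all(r.support == (True, True) for r in out)

    def test_disjoint_lists_empty(self):
        assert intersect_replicates([self._region(0, 100)], [self._region(200, 300)]) == []

    def test_partial_overlap_trimmed(self):
        out = intersect_replicates([self._region(100, 300)], [self._region(250, 400)])
        assert [(r.start, r.end) for r in out] == [(250, 300)]
        assert out[0].support == (True, True)

    def test_symmetric_base_coverage(self, rng):
        def random_regions(n):
            starts = np.sort(rng.integers(0, 5000, n))
            return [self._region(int(s), int(s + rng.integers(50, 400))) for s in starts]

        a, b = random_regions(12), random_regions(12)

        def covered(regions):
            bases = set()
            for r in regions:
                bases.update(range(r.start, r.end))
            return bases

        assert covered(intersect_replicates(a, b)) == covered(intersect_replicates(b, a))


class TestEndToEndCalling:
    def test_planted_sites_recovered(self, config):
        """Called regions land within a fragment length of planted sites."""
        p = SimulationParams(genome_length=500_000, n_chromosomes=1, n_genes=60,
                             site_count=8, enrichment_factor=20.0,
                             n_chip_reads=100_000, n_input_reads=100_000,
                             frac_sites_both_active=1.0, seed=21)
        genome, genes, truth = simulate_genome(p)
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        from chiptarget.peaks import detect_binding_regions
        chip = [simulate_chip_reads(genome, truth, p, "untreated", r) for r in (1, 2)]
        inp = [simulate_input_reads(genome, p, r) for r in (1, 2)]
        regions = detect_binding_regions(chip, inp, chrom_lengths, config,
                                         condition="untreated", seed=9)
        sites = np.array([s.position for s in truth.sites])
        recovered = 0
        for s in sites:
            if any(abs(r.midpoint - s) <= p.fragment_length for r in regions):
                recovered += 1
        assert recovered >= 7

    def test_determinism(self, config):
        p = SimulationParams(genome_length=200_000, n_chromosomes=1, n_genes=30,
                             site_count=5, n_chip_reads=40_000, n_input_reads=40_000,
                             frac_sites_both_active=1.0, seed=33)
        genome, _, truth = simulate_genome(p)
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        from chiptarget.peaks import detect_binding_regions
        chip = [simulate_chip_reads(genome, truth, p, "untreated", r) for r in (1, 2)]
        inp = [simulate_input_reads(genome, p, r) for r in (1, 2)]
        r1 = detect_binding_regions(chip, inp, chrom_lengths, config, seed=2)
        r2 = detect_binding_regions(chip, inp, chrom_lengths, config, seed=2)
        assert [(a.chrom, a.start, a.end, a.strand_sep_q) for a in r1] == \
               [(a.chrom, a.start, a.end, a.strand_sep_q) for a in r2]
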