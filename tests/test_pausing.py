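"""Pausing-index statistics, filters, permutation test, and method overlap."""

import math

import numpy as np
import pytest

from hetdomain import pausing
from hetdomain.core import (
    DomainPartition,
    GeneModel,
    GenomicInterval,
    ProbeTrack,
    ReadDensityTrack,
)
from hetdomain.pausing import PausingResult


def make_gene(gid, start, end, strand="+", chrom="chr4"):
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel(gene_id=gid, interval=iv, exons=[iv])


def density_from(plus, chrom="chr4"):
    plus = np.asarray(plus)
    return ReadDensityTrack(
        counts={(chrom, "+"): plus, (chrom, "-"): np.zeros_like(plus)},
        chrom_lengths={chrom: plus.size},
    )


class TestFilter:
    def test_short_gene_excluded(self):
        genes = [make_gene("short", 0, 499), make_gene("ok", 10_000, 12_000)]
        kept = pausing.filter_genes_for_pi(genes)
        assert [g.gene_id for g in kept] == ["ok"]

    def test_one_bp_overlap_excludes_both(self):
        genes = [make_gene("a", 0, 1000), make_gene("b", 999, 2000),
                 make_gene("c", 5000, 7000)]
        kept = pausing.filter_genes_for_pi(genes)
        assert [g.gene_id for g in kept] == ["c"]

    def test_overlap_on_opposite_strand_still_excludes(self):
        genes = [make_gene("a", 0, 1000, "+"), make_gene("b", 500, 1500, "-")]
        assert pausing.filter_genes_for_pi(genes) == []

    def test_nested_gene_excludes_both(self):
        genes = [make_gene("outer", 0, 10_000), make_gene("inner", 2_000, 3_000)]
        assert pausing.filter_genes_for_pi(genes) == []


class TestPiGroseq:
    def test_uniform_density_gives_one(self):
        d = density_from(np.full(5000, 3))
        assert pausing.pi_groseq(d, make_gene("g", 0, 2500)) == 1.0

    def test_constructed_ratio_of_ten(self):
        counts = np.zeros(3000, dtype=int)
        counts[:500] = 100  # 100 reads/bp over first 500
        counts[500:1000] = 10  # body window = ceil(0.25*2000) = 500 bp
        d = density_from(counts)
        assert pausing.pi_groseq(d, make_gene("g", 0, 2500)) == 10.0

    def test_all_reads_in_five_prime_is_infinite(self):
        counts = np.zeros(3000, dtype=int)
        counts[:500] = 5
        d = density_from(counts)
        assert pausing.pi_groseq(d, make_gene("g", 0, 2500)) == math.inf

    def test_zero_over_zero_is_undefined(self):
        d = density_from(np.zeros(3000, dtype=int))
        assert pausing.pi_groseq(d, make_gene("g", 0, 2500)) is None

    def test_antisense_reads_ignored(self):
        minus_only = ReadDensityTrack(
            counts={("chr4", "+"): np.zeros(3000, dtype=int),
                    ("chr4", "-"): np.full(3000, 9)},
            chrom_lengths={"chr4": 3000},
        )
        assert pausing.pi_groseq(minus_only, make_gene("g", 0, 2500, "+")) is None

    def test_minus_strand_windows_oriented(self):
        counts = np.zeros(3000, dtype=int)
        counts[2000:2500] = 50  # last 500 bp = 5' window of a minus gene
        d = ReadDensityTrack(
            counts={("chr4", "-"): counts,
                    ("chr4", "+"): np.zeros_like(counts)},
            chrom_lengths={"chr4": 3000},
        )
        assert pausing.pi_groseq(d, make_gene("g", 0, 2500, "-")) == math.inf

    def test_matches_brute_force_oracle(self, sim_ann, sim_density):
        """Implementation equals per-base python-loop summation exactly."""
        genes = pausing.filter_genes_for_pi(sim_ann.genes)[:200]
        for g in genes:
            got = pausing.pi_groseq(sim_density, g)
            strand = "+" if g.oriented_forward else "-"
            arr = sim_density.counts[(g.chrom, strand)]
            L = g.length
            body_len = math.ceil(0.25 * (L - 500))
            if g.oriented_forward:
                five = sum(arr[g.interval.start + i] for i in range(500))
                body = sum(arr[g.interval.start + 500 + i] for i in range(body_len))
            else:
                five = sum(arr[g.interval.end - 500 + i] for i in range(500))
                body = sum(arr[g.interval.end - 500 - body_len + i]
                           for i in range(body_len))
            if five == 0 and body == 0:
                assert got is None
                continue
            if body == 0:
                assert got == math.inf
                continue
            expected = (five / 500) / (body / body_len)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, 4000)
        g = make_gene("g", 0, 3000)
        a = pausing.pi_groseq(density_from(counts), g)
        b = pausing.pi_groseq(density_from(counts * 7), g)
        assert a == pytest.approx(b, rel=1e-12)


class TestPiChip:
    def track(self, pos, vals, chrom="chr4"):
        return ProbeTrack("PolII", "WT",
                          {chrom: (np.asarray(pos), np.asarray(vals, float))})

    def test_constant_track_gives_one(self):
        t = self.track(np.arange(0, 5000, 100), np.full(50, 1.5))
        assert pausing.pi_chip(t, make_gene("g", 0, 4000)) == pytest.approx(1.0)

    def test_linear_scale_ratio(self):
        # TSS max M=2 -> linear 4; body all M=0 -> linear median 1 -> PI 4
        pos = np.arange(0, 4000, 100)
        vals = np.zeros(pos.size)
        vals[pos <= 300] = 2.0
        t = self.track(pos, vals)
        assert pausing.pi_chip(t, make_gene("g", 0, 4000)) == pytest.approx(4.0)

    def test_body_dominates_gives_pi_below_one(self):
        pos = np.arange(0, 4000, 100)
        vals = np.where(pos >= 600, 2.0, 0.0)
        t = self.track(pos, vals)
        assert pausing.pi_chip(t, make_gene("g", 0, 4000)) < 1.0

    def test_insufficient_probes_skipped(self):
        t = self.track([100], [1.0])
        assert pausing.pi_chip(t, make_gene("g", 0, 4000)) is None

    def test_matches_direct_computation(self, sim_ann, sim_tracks):
        from hetdomain.enrichment import smooth_track

        t = smooth_track(sim_tracks[("PolII", "WT")])
        genes = pausing.filter_genes_for_pi(sim_ann.genes)[:200]
        for g in genes:
            got = pausing.pi_chip(t, g)
            tss_vals = t.slice_values(g.chrom, g.tss - 300, g.tss + 301)
            if g.oriented_forward:
                body = t.slice_values(g.chrom, g.tss + 600, g.interval.end)
            else:
                body = t.slice_values(g.chrom, g.interval.start, g.tss - 599)
            if tss_vals.size < 1 or body.size < 2:
                assert got is None
                continue
            expected = 2 ** tss_vals.max() / np.median(2.0 ** body)
            assert got == pytest.approx(expected, rel=1e-12)


class TestPausedFraction:
    def results(self, pis, domain="d", threshold=10.0):
        return [
            PausingResult(f"g{i}", pi, "groseq",
                          pi is not None and pi > threshold, threshold, domain)
            for i, pi in enumerate(pis)
        ]

    def test_all_below_threshold(self):
        frac = pausing.paused_fraction(self.results([1.0] * 20))
        assert frac["d"] == (20, 0.0)

    def test_threshold_zero_everything_paused(self):
        res = self.results([1.0] * 10)
        frac = pausing.paused_fraction(res, threshold=0.0)
        assert frac["d"] == (10, 1.0)

    def test_undefined_excluded_from_denominator(self):
        res = self.results([1.0, None, 20.0, None])
        frac = pausing.paused_fraction(res)
        assert frac["d"] == (2, 0.5)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        res = self.results(list(rng.lognormal(1, 1.5, 200)))
        sweep = pausing.paused_fraction_sweep(res, [1, 2, 5, 10, 20, 50])
        fracs = [sweep[t]["d"][1] for t in (1, 2, 5, 10, 20, 50)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_mixed_methods_rejected(self):
        res = self.results([1.0]) + [
            PausingResult("x", 1.0, "chip", False, 4.0, "d")
        ]
        with pytest.raises(ValueError):
            pausing.paused_fraction(res)


class TestPermutationTest:
    def test_plus_one_formula_floor(self):
        """Observed beyond every null value: p = 1/(n_perm+1)."""
        res = [PausingResult(f"a{i}", 20.0, "groseq", True, 10.0, "A")
               for i in range(50)]
        res += [PausingResult(f"b{i}", 1.0, "groseq", False, 10.0, "B")
                for i in range(50)]
        _obs, p = pausing.pausing_domain_test(res, "A", "B", n_perm=100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_detects_planted_contrast(self, sim_ann, sim_density):
        res = pausing.compute_pausing(sim_ann.genes, sim_ann.partition,
                                      "groseq", density=sim_density)
        _obs, p = pausing.pausing_domain_test(res, "euchromatin", "chr4",
                                              n_perm=999, seed=0)
        assert p < 0.05

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            pausing.pausing_domain_test([], "A", "B", n_perm=10)


class TestPiRatio:
    def res(self, gid, pi, method="chip"):
        return PausingResult(gid, pi, method, False, 4.0, "d")

    def test_identical_conditions(self):
        wt = [self.res(f"g{i}", float(i + 1)) for i in range(10)]
        ratios, n_up, n_ex = pausing.pi_ratio_mutant(wt, wt)
        assert all(v == 1.0 for v in ratios.values())
        assert n_up == 0 and n_ex == 0

    def test_undefined_or_infinite_excluded(self):
        wt = [self.res("a", math.inf), self.res("b", 2.0), self.res("c", None)]
        mut = [self.res("a", 1.0), self.res("b", 4.0), self.res("c", 1.0)]
        ratios, n_up, n_ex = pausing.pi_ratio_mutant(wt, mut)
        assert set(ratios) == {"b"} and n_up == 1 and n_ex == 2

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            pausing.pi_ratio_mutant([self.res("a", 1.0)], [self.res("b", 1.0)])


class TestTssPeak:
    def track(self, pos, vals):
        return ProbeTrack("PolII", "WT",
                          {"chr4": (np.asarray(pos), np.asarray(vals, float))})

    def test_peak_at_tss_offset_zero(self):
        pos = np.arange(9_500, 10_501, 100)
        vals = -np.abs(pos - 10_000) / 100.0
        t = self.track(pos, vals)
        offset, flat = pausing.tss_peak_position(t, make_gene("g", 10_000, 20_000))
        assert offset == 0 and not flat

    def test_flat_window_tie_rule(self):
        pos = np.arange(9_500, 10_501, 100)
        t = self.track(pos, np.zeros(pos.size))
        offset, flat = pausing.tss_peak_position(t, make_gene("g", 10_000, 20_000))
        assert offset == -500 and flat

    def test_planted_mutant_shift_recovered(self):
        """Mutant peak moved +70 bp: mean shift recovered within spacing."""
        rng = np.random.default_rng(2)
        genes = [make_gene(f"g{i}", 20_000 + 10_000 * i, 24_000 + 10_000 * i,
                           strand="+" if i % 2 else "-")
                 for i in range(30)]
        pos = np.arange(25, 400_000, 50)

        def peaked(shift):
            vals = rng.normal(0, 0.05, pos.size)
            for g in genes:
                peak = g.tss + shift if g.oriented_forward else g.tss - shift
                vals += 2.0 * np.exp(-0.5 * ((pos - peak) / 80.0) ** 2)
            return self.track(pos, vals)

        shift = pausing.peak_shift(peaked(0), peaked(70), genes)
        assert abs(shift - 70) <= 50  # within probe spacing


class TestMethodOverlap:
    def res(self, gid, pi, method):
        return PausingResult(gid, pi, method, False, 1.0, "d")

    def test_identical_rankings(self):
        a = [self.res(f"g{i}", float(100 - i), "groseq") for i in range(100)]
        b = [self.res(f"g{i}", float(100 - i), "chip") for i in range(100)]
        overlap = pausing.method_overlap(a, b, [10, 50])
        assert overlap == {10: 1.0, 50: 1.0}

    def test_reversed_rankings_zero_overlap(self):
        a = [self.res(f"g{i}", float(100 - i), "groseq") for i in range(100)]
        b = [self.res(f"g{i}", float(i), "chip") for i in range(100)]
        assert pausing.method_overlap(a, b, [20])[20] == 0.0

    def test_random_rankings_near_n_over_g(self):
        rng = np.random.default_rng(3)
        G, N = 1000, 200
        ids = [f"g{i}" for i in range(G)]
        a = [self.res(g, float(v), "groseq")
             for g, v in zip(ids, rng.permutation(G))]
        b = [self.res(g, float(v), "chip")
             for g, v in zip(ids, rng.permutation(G))]
        overlap = pausing.method_overlap(a, b, [N])[N]
        # hypergeometric: mean N/G = 0.2, sd ~ 0.025
        assert abs(overlap - N / G) < 0.1

    def test_transcripts_reduced_by_max(self):
        a = [self.res("g1", 1.0, "groseq"), self.res("g1", 50.0, "groseq"),
             self.res("g2", 10.0, "groseq")]
        b = [self.res("g1", 5.0, "chip"), self.res("g2", 1.0, "chip")]
        assert pausing.method_overlap(a, b, [1])[1] == 1.0  # g1 tops both
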