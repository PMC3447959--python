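"""Synthetic-data generator: determinism, planted structure, config errors."""

import numpy as np
import pytest
from scipy import stats

from hetdomain import simulate
from hetdomain.core import GenomicInterval
from hetdomain.simulate import ConfigError, DomainConfig, SimConfig


def small_cfg(**kw):
    """One euchromatin-like and one chr4-like domain, desk-sized."""
    domains = [
        DomainConfig(label="euchromatin", chrom="chrE", start=0, length=600_000,
                     n_genes=150, gene_length_median=1907, exon_median=3,
                     repeat_density=0.05, gc=0.43, active_fraction=0.52,
                     paused_fraction=0.15,
                     motif_rates={"TRL": 0.24, "PB": 0.10}),
        DomainConfig(label="chr4", chrom="chr4", start=0, length=1_200_000,
                     n_genes=80, gene_length_median=8001, exon_median=6,
                     repeat_density=0.30, gc=0.36, active_fraction=0.54,
                     paused_fraction=0.02,
                     motif_rates={"TRL": 0.11, "PB": 0.10}),
    ]
    return SimConfig(seed=kw.pop("seed", 7), domains=domains, **kw)


class TestAnnotation:
    def test_exact_gene_counts(self):
        ann = simulate.generate_annotation(small_cfg())
        assert len(ann.genes_in_domain("chr4")) == 80
        assert len(ann.genes_in_domain("euchromatin")) == 150

    def test_gene_length_and_exon_medians(self):
        # medians over several seeds concentrate on the configured values
        lengths, exons = [], []
        for seed in range(5):
            ann = simulate.generate_annotation(small_cfg(seed=seed))
            genes = ann.genes_in_domain("chr4")
            lengths.append(np.median([g.length for g in genes]))
            exons.append(np.median([g.n_exons for g in genes]))
        assert abs(np.mean(lengths) - 8001) / 8001 < 0.15
        assert abs(np.mean(exons) - 6) <= 1

    def test_repeat_density_within_5_points(self):
        ann = simulate.generate_annotation(small_cfg())
        for label, chrom, length, density in (
            ("chr4", "chr4", 1_200_000, 0.30),
            ("euchromatin", "chrE", 600_000, 0.05),
        ):
            bp = sum(len(r) for r in ann.repeats if r.chrom == chrom)
            assert abs(bp / length - density) < 0.05

    def test_zero_repeat_density_gives_empty_set(self):
        cfg = small_cfg()
        for d in cfg.domains:
            d.repeat_density = 0.0
        ann = simulate.generate_annotation(cfg)
        assert ann.repeats == []

    def test_determinism(self):
        a = simulate.generate_annotation(small_cfg(seed=3))
        b = simulate.generate_annotation(small_cfg(seed=3))
        assert [g.interval for g in a.genes] == [g.interval for g in b.genes]
        assert a.repeats == b.repeats
        assert a.paused == b.paused

    def test_genes_non_overlapping_by_default(self):
        ann = simulate.generate_annotation(small_cfg())
        by_chrom = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_overlapping_pairs_planted_on_request(self):
        ann = simulate.generate_annotation(small_cfg(n_overlapping_pairs=5))
        overlaps = 0
        by_chrom = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort()
            overlaps += sum(a.end > b.start for a, b in zip(ivs, ivs[1:]))
        assert overlaps >= 5

    def test_infeasible_packing_raises(self):
        cfg = small_cfg()
        cfg.domains[1].n_genes = 500  # 500 x ~9 kb >> 1.2 Mb
        with pytest.raises(ConfigError):
            simulate.generate_annotation(cfg)


class TestTracks:
    def test_retention_one_matches_wt_within_noise(self):
        cfg = small_cfg()
        cfg.mutants = {"mut": {"HP1a": {"chr4": {"active_body": 1.0}}}}
        ann = simulate.generate_annotation(cfg)
        tracks = simulate.generate_tracks(cfg, ann, marks=["HP1a"],
                                          conditions=["WT", "mut"])
        cls = simulate.feature_class_arrays(cfg, ann)["chr4"]
        for cond in ("WT", "mut"):
            t = tracks[("HP1a", cond)]
            pos = t.positions("chr4")
            body = t.values("chr4")[cls[pos] == simulate.CLASS_ACTIVE_BODY]
            assert abs(body.mean() - 2.0) < 0.05

    def test_retention_zero_drops_to_background(self):
        cfg = small_cfg()
        cfg.mutants = {"mut": {"HP1a": {"chr4": {"active_body": 0.0}}}}
        ann = simulate.generate_annotation(cfg)
        tracks = simulate.generate_tracks(cfg, ann, marks=["HP1a"],
                                          conditions=["mut"])
        cls = simulate.feature_class_arrays(cfg, ann)["chr4"]
        t = tracks[("HP1a", "mut")]
        body = t.values("chr4")[cls[t.positions("chr4")] == simulate.CLASS_ACTIVE_BODY]
        assert abs(body.mean()) < 0.05

    def test_unknown_condition_rejected(self, sim_cfg, sim_ann):
        with pytest.raises(ConfigError):
            simulate.generate_tracks(sim_cfg, sim_ann, conditions=["nonesuch"])

    def test_determinism(self):
        cfg = small_cfg()
        ann = simulate.generate_annotation(cfg)
        a = simulate.generate_tracks(cfg, ann, marks=["HP1a"], conditions=["WT"])
        b = simulate.generate_tracks(cfg, ann, marks=["HP1a"], conditions=["WT"])
        assert np.array_equal(a[("HP1a", "WT")].values("chr4"),
                              b[("HP1a", "WT")].values("chr4"))


class TestReadDensity:
    def test_multiplier_below_one_rejected(self):
        cfg = small_cfg(pause_multiplier=0.5)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_expected_pi_matches_rate_ratio(self):
        """Planted pause: closed-form PI from the rate architecture.

        First 500 bp carries lambda*(500 + m*w)/500 mean density; the body
        window carries lambda, so E[PI] ~= 1 + m*w/500.
        """
        from hetdomain.pausing import compute_pausing

        cfg = small_cfg(pause_multiplier=150.0, lambda_body=1.0)
        for d in cfg.domains:
            d.paused_fraction = 1.0
        ann = simulate.generate_annotation(cfg)
        density = simulate.generate_readdensity(cfg, ann)
        results = compute_pausing(ann.genes, ann.partition, "groseq",
                                  density=density)
        expected = 1 + 150.0 * cfg.pause_window / 500.0  # = 16
        pis = [r.pi for r in results if r.pi is not None
               and ann.paused[r.gene_id]]
        assert abs(np.mean(pis) - expected) / expected < 0.05

    def test_zero_paused_fraction_recovers_zero(self):
        from hetdomain.pausing import compute_pausing, paused_fraction

        cfg = small_cfg()
        for d in cfg.domains:
            d.paused_fraction = 0.0
        ann = simulate.generate_annotation(cfg)
        density = simulate.generate_readdensity(cfg, ann)
        results = compute_pausing(ann.genes, ann.partition, "groseq",
                                  density=density)
        for _dom, (_n, frac) in paused_fraction(results).items():
            assert frac < 0.01

    def test_determinism(self):
        cfg = small_cfg()
        ann = simulate.generate_annotation(cfg)
        a = simulate.generate_readdensity(cfg, ann)
        b = simulate.generate_readdensity(cfg, ann)
        assert np.array_equal(a.counts[("chr4", "+")], b.counts[("chr4", "+")])


class TestSequences:
    def test_planting_rate_one_gives_hit_everywhere(self):
        from hetdomain.seqfeat import MotifSpec, scan_motif

        cfg = small_cfg()
        for d in cfg.domains:
            d.motif_rates = {"PB": 1.0}
        ann = simulate.generate_annotation(cfg)
        seqs = simulate.generate_sequences(cfg, ann)
        spec = MotifSpec.default("PB")
        for s in seqs.values():
            window = s[200 - 60: 200 + 60]
            assert scan_motif(window, spec)

    def test_background_pb_rate_matches_combinatorics(self):
        """With rate 0 and uniform GC, PB hits follow (L-6)*8/4^7 per strand."""
        from hetdomain.seqfeat import MotifSpec, scan_motif

        cfg = small_cfg()
        for d in cfg.domains:
            d.motif_rates = {}
            d.gc = 0.5
        ann = simulate.generate_annotation(cfg)
        seqs = simulate.generate_sequences(cfg, ann)
        spec = MotifSpec.default("PB")
        L = 400
        total = sum(len(scan_motif(s, spec)) for s in seqs.values())
        expected = len(seqs) * (L - 6) * 8 / 4 ** 7
        assert abs(total - expected) <= 4 * np.sqrt(expected)

    def test_gc_controls_promoter_composition(self):
        cfg = small_cfg()
        ann = simulate.generate_annotation(cfg)
        seqs = simulate.generate_sequences(cfg, ann)
        def gc(s):
            return (s.count("G") + s.count("C")) / len(s)
        chr4_gc = np.mean([gc(seqs[g.gene_id]) for g in ann.genes_in_domain("chr4")])
        eu_gc = np.mean([gc(seqs[g.gene_id])
                         for g in ann.genes_in_domain("euchromatin")])
        assert chr4_gc < eu_gc


class TestExpression:
    def test_active_fraction_exceeds_threshold(self, sim_ann, sim_expression):
        from hetdomain.metagene import classify_expressed

        wt, _mut, _f = sim_expression
        active = classify_expressed(wt, "cell_line")
        assert all(active[g] == sim_ann.active[g] for g in active)

    def test_down_fraction_applied_to_chr4(self):
        cfg = small_cfg()
        ann = simulate.generate_annotation(cfg)
        wt, mut, factors = simulate.generate_expression(cfg, ann)
        chr4 = [g.gene_id for g in ann.genes_in_domain("chr4")]
        n_down = sum(mut[g] < wt[g] for g in chr4)
        assert n_down == round(0.8 * len(chr4))
        eu = [g.gene_id for g in ann.genes_in_domain("euchromatin")]
        assert all(mut[g] == wt[g] for g in eu)

    def test_null_factors_with_noise_calibrate_paired_test(self):
        """factor 1 + symmetric noise: per-domain Wilcoxon p is uniform."""
        from hetdomain.mutant import expression_change

        pvals = []
        for seed in range(60):
            cfg = small_cfg(seed=seed, expression_noise_sd_log2=0.2,
                            mutant_down_fraction={})
            cfg.domains = cfg.domains[1:]  # chr4-like only, 80 genes
            ann = simulate.generate_annotation(cfg)
            wt, mut, _ = simulate.generate_expression(cfg, ann)
            _fc, tests = expression_change(wt, mut, ann.domain_of)
            pvals.append(tests.loc["chr4", "p_wilcoxon"])
        # uniformity: KS test should not reject wildly, and ~5% below 0.05
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_determinism(self):
        cfg = small_cfg()
        ann = simulate.generate_annotation(cfg)
        a = simulate.generate_expression(cfg, ann)
        b = simulate.generate_expression(cfg, ann)
        assert a[0].values == b[0].values and a[1].values == b[1].values
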