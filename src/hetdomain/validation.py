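"""Planted-truth self-checks for the whole pipeline.

Every function generates synthetic data with known ground truth, runs the
corresponding pipeline stage from scratch, and returns the measured
quantities. The brute-force oracles here are written independently of the
implementation paths they check (plain python loops and direct formula
summation). Problem sizes follow the package's desk-scale study conditions:
a euchromatin-like arm of a few thousand genes and a chr4-like arm of ~80
genes.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import enrichment, metagene, mutant, pausing, seqfeat, simulate, states
from .core import (
    EnrichedRegion,
    EnrichedRegionSet,
    GenomicInterval,
    ProbeTrack,
)
from .pausing import PausingResult
from .simulate import DomainConfig, SimConfig


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# shared configs


def two_domain_cfg(seed: int, n_eu: int = 300, paused_eu: float = 0.15,
                   paused_chr4: float = 0.02, **kw) -> SimConfig:
    eu_len = int(n_eu * 2300 / 0.62)  # genes occupy ~62% of the arm
    domains = [
        DomainConfig(label="euchromatin", chrom="chrE", start=0, length=eu_len,
                     n_genes=n_eu, gene_length_median=1907, exon_median=3,
                     repeat_density=0.05, gc=0.43, active_fraction=0.52,
                     paused_fraction=paused_eu,
                     motif_rates={"TRL": 0.24, "PB": 0.10}),
        DomainConfig(label="chr4", chrom="chr4", start=0, length=1_200_000,
                     n_genes=80, gene_length_median=8001, exon_median=6,
                     repeat_density=0.30, gc=0.36, active_fraction=0.54,
                     paused_fraction=paused_chr4,
                     motif_rates={"TRL": 0.11, "PB": 0.10}),
    ]
    return SimConfig(seed=seed, domains=domains, **kw)


# ---------------------------------------------------------------------------
# 1. pausing-index oracle equivalence


def pi_oracle_check(seed: int, n_genes: int = 200) -> dict:
    """Compare both PI implementations against brute-force recomputation."""
    cfg = two_domain_cfg(seed, n_eu=max(50, n_genes - 80))
    ann = simulate.generate_annotation(cfg)
    density = simulate.generate_readdensity(cfg, ann)
    tracks = simulate.generate_tracks(cfg, ann, marks=["PolII"],
                                      conditions=["WT"])
    polII = enrichment.smooth_track(tracks[("PolII", "WT")])
    genes = pausing.filter_genes_for_pi(ann.genes)[:n_genes]

    max_rel_groseq = 0.0
    max_rel_chip = 0.0
    n_checked = 0
    for g in genes:
        # GRO-seq oracle: per-base python summation
        strand = "+" if g.oriented_forward else "-"
        arr = density.counts[(g.chrom, strand)]
        body_len = math.ceil(0.25 * (g.length - 500))
        if g.oriented_forward:
            five = sum(int(arr[g.interval.start + i]) for i in range(500))
            body = sum(int(arr[g.interval.start + 500 + i])
                       for i in range(body_len))
        else:
            five = sum(int(arr[g.interval.end - 500 + i]) for i in range(500))
            body = sum(int(arr[g.interval.end - 500 - body_len + i])
                       for i in range(body_len))
        got = pausing.pi_groseq(density, g)
        if five == 0 and body == 0:
            assert got is None
        elif body == 0:
            assert got == math.inf
        else:
            expected = (five / 500) / (body / body_len)
            max_rel_groseq = max(max_rel_groseq,
                                 abs(got - expected) / expected)
        # ChIP oracle: direct max / median on the probe windows
        got_chip = pausing.pi_chip(polII, g)
        pos, val = polII.data[g.chrom]
        tss_vals = [v for p, v in zip(pos, val)
                    if g.tss - 300 <= p < g.tss + 301]
        if g.oriented_forward:
            body_vals = [v for p, v in zip(pos, val)
                         if g.tss + 600 <= p < g.interval.end]
        else:
            body_vals = [v for p, v in zip(pos, val)
                         if g.interval.start <= p < g.tss - 599]
        if len(tss_vals) >= 1 and len(body_vals) >= 2:
            expected = 2 ** max(tss_vals) / float(
                np.median([2.0 ** v for v in body_vals])
            )
            max_rel_chip = max(max_rel_chip,
                               abs(got_chip - expected) / expected)
        n_checked += 1
    return {
        "n": n_checked,
        "max_rel_err_groseq": max_rel_groseq,
        "max_rel_err_chip": max_rel_chip,
    }


# ---------------------------------------------------------------------------
# 2. pausing-fraction recovery


def pausing_recovery(seed: int, n_runs: int = 10, n_eu: int = 2000,
                     n_perm: int = 999) -> dict:
    """Plant 15% / 2% paused fractions, recover them, and test the contrast."""
    fr_eu, fr_c4, pvals = [], [], []
    for run in range(n_runs):
        cfg = two_domain_cfg(_sub_seed(seed, run), n_eu=n_eu,
                             paused_eu=0.15, paused_chr4=0.02)
        for d in cfg.domains:  # realise the stated sample sizes: every gene
            d.active_fraction = 1.0  # is polymerase-associated

        ann = simulate.generate_annotation(cfg)
        density = simulate.generate_readdensity(cfg, ann)
        results = pausing.compute_pausing(ann.genes, ann.partition, "groseq",
                                          density=density)
        frac = pausing.paused_fraction(results)
        fr_eu.append(frac["euchromatin"][1])
        fr_c4.append(frac["chr4"][1])
        _obs, p = pausing.pausing_domain_test(
            results, "euchromatin", "chr4", n_perm=n_perm,
            seed=_sub_seed(seed, 1000 + run),
        )
        pvals.append(p)
    return {
        "planted_euchromatin": 0.15,
        "planted_chr4": 0.02,
        "mean_frac_euchromatin": float(np.mean(fr_eu)),
        "mean_frac_chr4": float(np.mean(fr_c4)),
        "p_values": pvals,
        "n_runs_significant": int(sum(p < 0.01 for p in pvals)),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# 3. permutation calibration


def _constructed_results(rng, n_a, n_b, frac):
    out = []
    for i, flag in enumerate(rng.random(n_a) < frac):
        out.append(PausingResult(f"a{i}", 20.0 if flag else 1.0, "groseq",
                                 bool(flag), 10.0, "A"))
    for i, flag in enumerate(rng.random(n_b) < frac):
        out.append(PausingResult(f"b{i}", 20.0 if flag else 1.0, "groseq",
                                 bool(flag), 10.0, "B"))
    return out


def permutation_calibration(seed: int, n_rep: int = 500,
                            n_perm: int = 199) -> dict:
    """Empirical type-I error at alpha = 0.05 under the null for both
    permutation tests (equal planted paused fractions; uniformly placed
    peaks for the repeat-distance test)."""
    rng = np.random.default_rng(seed)
    rej_pausing = 0
    for rep in range(n_rep):
        res = _constructed_results(rng, 300, 100, 0.10)
        _o, p = pausing_domain_test_seeded(res, _sub_seed(seed, rep), n_perm)
        rej_pausing += (p <= 0.05)

    # sparse repeats keep the median-distance statistic off its floor
    dom = GenomicInterval("chr4", 0, 1_200_000)
    repeats, pos = [], 0
    while True:
        pos += int(rng.integers(4_000, 12_000))
        length = int(rng.integers(200, 600))
        if pos + length >= dom.end:
            break
        repeats.append(GenomicInterval("chr4", pos, pos + length))
        pos += length
    rej_dist = 0
    for rep in range(n_rep):
        starts, lens = mutant._random_placements(
            rng, np.full(30, 100), dom.start, dom.end
        )
        peaks = EnrichedRegionSet(
            [EnrichedRegion(GenomicInterval("chr4", int(s), int(s + L)), 1.0)
             for s, L in zip(starts, lens)],
            1e-3,
        )
        _obs, _exp, p = mutant.distance_to_repeat_test(
            peaks, repeats, dom, n_perm=n_perm, seed=_sub_seed(seed, 5000 + rep)
        )
        rej_dist += (p <= 0.05)
    return {
        "n_replicates": n_rep,
        "pausing_type_i": rej_pausing / n_rep,
        "distance_type_i": rej_dist / n_rep,
    }


def pausing_domain_test_seeded(res, seed, n_perm):
    return pausing.pausing_domain_test(res, "A", "B", n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# 4. scaling-factor recovery


def scaling_recovery(seed: int, n_probes: int = 20_000) -> dict:
    rng = np.random.default_rng(seed)
    pos = np.arange(n_probes) * 100
    wt_vals = rng.normal(0, 1, n_probes)
    wt = ProbeTrack("HP1a", "WT", {"chr4": (pos, wt_vals)})
    out = {}
    for c in (0.5, 1.0, 2.0):
        noisy = wt.with_values(
            {"chr4": c * wt_vals + 0.7 + rng.normal(0, 0.02, n_probes)},
            condition="mut",
        )
        factor, _ = enrichment.scale_mutant_to_wt(wt, noisy)
        out[f"rel_err_c{c:g}"] = abs(factor.value - 1.0 / c) * c
        clean = wt.with_values({"chr4": c * wt_vals + 0.7}, condition="mut")
        f_clean, _ = enrichment.scale_mutant_to_wt(wt, clean)
        out[f"noiseless_rel_err_c{c:g}"] = abs(f_clean.value - 1.0 / c) * c
    base = wt.with_values({"chr4": 0.25 * wt_vals}, condition="mut")
    shifted = base.with_values({"chr4": base.values("chr4") + 123.0})
    f1, _ = enrichment.scale_mutant_to_wt(wt, base)
    f2, _ = enrichment.scale_mutant_to_wt(wt, shifted)
    out["offset_invariance_rel_dev"] = abs(f1.value - f2.value) / f1.value
    return out


# ---------------------------------------------------------------------------
# 5. quantile-normalization exactness


def quantile_check(seed: int, n_probes: int = 5_000, n_tracks: int = 4) -> dict:
    rng = np.random.default_rng(seed)
    pos = np.arange(n_probes) * 100
    tracks = []
    for i in range(n_tracks):
        # continuous draws: ties have measure zero, so sorted outputs must
        # equal the reference bit-for-bit (tie handling is checked separately)
        vals = rng.normal(i, 1 + 0.3 * i, n_probes)
        tracks.append(ProbeTrack("m", f"r{i}", {"chr4": (pos, vals)}))
    out = enrichment.quantile_normalize(tracks)
    ref = np.sort(out[0].values("chr4"))
    max_disc = max(
        float(np.max(np.abs(np.sort(o.values("chr4")) - ref))) for o in out[1:]
    )
    again = enrichment.quantile_normalize(out)
    idem = max(
        float(np.max(np.abs(a.values("chr4") - b.values("chr4"))))
        for a, b in zip(out, again)
    )
    return {"max_sorted_discrepancy": max_disc, "idempotence_deviation": idem}


# ---------------------------------------------------------------------------
# 6. chromatin-state recovery


def state_recovery(seed: int, n_seeds: int = 10, n_per: int = 200) -> dict:
    """Five planted mark signatures >= 3 SD apart, k_initial 10, merge 0.8."""
    from .enrichment import BinMatrix
    import pandas as pd

    def bin_matrix(X):
        bins = [GenomicInterval("chrS", i * 500, (i + 1) * 500)
                for i in range(X.shape[0])]
        return BinMatrix(bins=bins,
                         matrix=pd.DataFrame(
                             X, columns=[f"m{i}" for i in range(X.shape[1])]),
                         width=500)

    successes = 0
    aris = []
    for k in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, k))
        truth = np.repeat(np.arange(5), n_per)
        X = 4.0 * np.eye(5)[truth] + rng.normal(0, 1, (5 * n_per, 5))
        sa = states.fit_states(bin_matrix(X), k_initial=10,
                               merge_threshold=0.8, seed=_sub_seed(seed, k))
        ari = adjusted_rand_score(truth, sa.labels)
        aris.append(ari)
        successes += (sa.k_final == 5 and ari >= 0.9)

    rng = np.random.default_rng(_sub_seed(seed, 99))
    single = states.fit_states(
        bin_matrix(rng.normal(2.0, 1.0, (400, 5))), k_initial=10,
        merge_threshold=0.8, seed=seed,
    )
    return {
        "n_seeds": n_seeds,
        "n_recovered": int(successes),
        "mean_ari": float(np.mean(aris)),
        "single_center_k_final": single.k_final,
    }


# ---------------------------------------------------------------------------
# 7. region-caller FDR


def region_caller_fdr(seed: int, n_null: int = 100, n_planted: int = 20,
                      n_probes: int = 10_000) -> dict:
    pos = np.arange(n_probes) * 100 + 50
    false_counts = []
    for rep in range(n_null):
        rng = np.random.default_rng(_sub_seed(seed, rep))
        t = ProbeTrack("m", "WT", {"chr4": (pos, rng.normal(0, 1, n_probes))})
        false_counts.append(len(enrichment.call_enriched_regions(t, fdr=1e-3)))

    block_starts = np.arange(500, 9_500, 1000)  # probe indices, 20 probes each
    recalls, false_bps = [], []
    for rep in range(n_planted):
        rng = np.random.default_rng(_sub_seed(seed, 10_000 + rep))
        vals = rng.normal(0, 1, n_probes)
        for s in block_starts:
            vals[s: s + 20] += 3.0
        t = enrichment.smooth_track(
            ProbeTrack("m", "WT", {"chr4": (pos, vals)}), 500
        )
        regions = enrichment.call_enriched_regions(t, fdr=1e-3)
        hit = sum(
            any(r.interval.start < (s + 20) * 100 and s * 100 < r.interval.end
                for r in regions)
            for s in block_starts
        )
        recalls.append(hit / block_starts.size)
        block_bp = np.zeros(n_probes * 100, bool)
        for s in block_starts:
            block_bp[s * 100: (s + 20) * 100] = True
        called = np.zeros(n_probes * 100, bool)
        for r in regions:
            called[r.interval.start: r.interval.end] = True
        false_bps.append(float((called & ~block_bp).sum() / (~block_bp).sum()))
    return {
        "n_null": n_null,
        "mean_false_regions_per_null_track": float(np.mean(false_counts)),
        "recall": float(np.mean(recalls)),
        "per_base_false_rate": float(np.mean(false_bps)),
    }


# ---------------------------------------------------------------------------
# 8. metagene / feature-class recovery


def metagene_recovery(seed: int) -> dict:
    """Planted mark architecture: body 2.0, TSS 0.2, flank 0.2 on active
    chr4-like genes; mutant retention factors on gene bodies."""
    cfg = two_domain_cfg(seed, background_mean=0.2)
    cfg.marks = {
        "HP1a": {"chr4": {"tss": 0.2, "active_body": 2.0, "silent": 0.2,
                          "repeat": 0.2}},
        "H3K9me2": {"chr4": {"tss": 0.2, "active_body": 1.2, "silent": 0.2,
                             "repeat": 0.2}},
        "H3K9me3": {"chr4": {"tss": 0.2, "active_body": 1.8, "silent": 0.2,
                             "repeat": 0.2}},
    }
    cfg.mutants = {
        "HP1a_null": {
            "H3K9me2": {"chr4": {"active_body": 0.111}},
            "H3K9me3": {"chr4": {"active_body": 0.333}},
        }
    }
    ann = simulate.generate_annotation(cfg)
    tracks = simulate.generate_tracks(cfg, ann)
    genes = [g for g in ann.genes_in_domain("chr4") if ann.active[g.gene_id]]

    prof = metagene.metagene_profile(
        enrichment.smooth_track(tracks[("HP1a", "WT")]), genes
    )
    body_mean = float(prof.mean[prof.body_slice].mean())
    flank_mean = float(prof.mean[prof.flank_index].mean())
    body_sem = float(prof.sem[prof.body_slice].mean())
    flank_sem = float(prof.sem[prof.flank_index].mean())
    body_vs_flank_sems = (body_mean - flank_mean) / math.hypot(body_sem,
                                                               flank_sem)

    fcm = metagene.feature_class_means(tracks[("HP1a", "WT")], ann.genes,
                                       ann.partition, ann.active)
    tss = fcm.loc[("chr4", "active_tss")]
    body = fcm.loc[("chr4", "active_body")]
    tss_vs_body_sems = (body["mean"] - tss["mean"]) / math.hypot(body["sem"],
                                                                 tss["sem"])
    retention = {}
    for mark, true_r in (("H3K9me2", 0.111), ("H3K9me3", 0.333)):
        wt = metagene.feature_class_means(tracks[(mark, "WT")], ann.genes,
                                          ann.partition, ann.active)
        mu = metagene.feature_class_means(tracks[(mark, "HP1a_null")],
                                          ann.genes, ann.partition, ann.active)
        got = (mu.loc[("chr4", "active_body"), "mean"]
               / wt.loc[("chr4", "active_body"), "mean"])
        retention[mark] = {"true": true_r, "recovered": float(got),
                           "rel_err": abs(got - true_r) / true_r}
    return {
        "body_mean": body_mean,
        "flank_mean": flank_mean,
        "body_vs_flank_sems": float(body_vs_flank_sems),
        "tss_vs_body_sems": float(tss_vs_body_sems),
        "retention": retention,
        "n_genes": prof.n_genes,
    }


# ---------------------------------------------------------------------------
# 9. motif and T_m oracles


def _brute_force_scan(seq, pattern):
    classes = [seqfeat.IUPAC[c] for c in pattern]
    return [i for i in range(len(seq) - len(pattern) + 1)
            if all(seq[i + j] in classes[j] for j in range(len(pattern)))]


def _tm_oracle(seq):
    """Independent nearest-neighbor summation over the published table."""
    from Bio.SeqUtils import MeltingTemp as mt

    nn = mt.DNA_NN3
    dh = ds = 0.0
    for init, bases in (("init_A/T", "AT"), ("init_G/C", "GC")):
        for end in (seq[0], seq[-1]):
            if end in bases:
                dh += nn[init][0]
                ds += nn[init][1]
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(len(seq) - 1):
        pair = seq[i: i + 2]
        rc = pair.translate(comp)
        key = f"{pair}/{rc}"
        if key not in nn:
            key = f"{rc[::-1]}/{pair[::-1]}"
        dh += nn[key][0]
        ds += nn[key][1]
    ds += 0.368 * (len(seq) - 1) * math.log(
        seqfeat.TM_PARAMS["Na_mM"] * 1e-3)
    k = (seqfeat.TM_PARAMS["dnac1_nM"]
         - seqfeat.TM_PARAMS["dnac2_nM"] / 2.0) * 1e-9
    return 1000 * dh / (ds + 1.987 * math.log(k)) - 273.15


def motif_tm_oracle(seed: int, n_seqs: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    mismatches = 0
    pb_hits = 0
    L = 121
    for _ in range(n_seqs):
        seq = "".join(rng.choice(list("ACGTN"), size=L,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        for name in ("PB", "TRL", "iTRL", "Inr"):
            spec = seqfeat.MotifSpec.default(name)
            if seqfeat.scan_motif(seq, spec) != _brute_force_scan(seq,
                                                                  spec.pattern):
                mismatches += 1
    for _ in range(n_seqs):
        seq = "".join(rng.choice(list("ACGT"), size=L))
        pb_hits += len(seqfeat.scan_motif(seq, seqfeat.MotifSpec.default("PB")))
    pb_expected = n_seqs * (L - 6) * 8 / 4 ** 7

    words = ["".join(rng.choice(list("ACGT"), size=9)) for _ in range(200)]
    tm_max_err = max(abs(seqfeat.tm_9mer(w) - _tm_oracle(w)) for w in words)

    def seqs(gc, n=15):
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return ["".join(rng.choice(list("ACGT"), size=100, p=p))
                for _ in range(n)]

    low = seqfeat.tm_profile(seqs(0.25))
    high = seqfeat.tm_profile(seqs(0.55))
    return {
        "scan_mismatches": mismatches,
        "pb_hits": pb_hits,
        "pb_expected": pb_expected,
        "pb_z": (pb_hits - pb_expected) / math.sqrt(pb_expected),
        "tm_max_abs_err": float(tm_max_err),
        "profile_length": int(low.mean_tm.size),
        "gc_monotone": bool(low.summary["mean"] < high.summary["mean"]),
    }


# ---------------------------------------------------------------------------
# 10. expression-contrast recovery


def expression_contrast(seed: int) -> dict:
    cfg = two_domain_cfg(seed)
    ann = simulate.generate_annotation(cfg)
    wt, mut_tbl, _factors = simulate.generate_expression(cfg, ann)
    _fc, tests = mutant.expression_change(wt, mut_tbl, ann.domain_of)
    n_chr4 = int(tests.loc["chr4", "n"])
    return {
        "n_chr4": n_chr4,
        "n_decreased": int(tests.loc["chr4", "n_decreased"]),
        "expected_decreased": round(0.8 * n_chr4),
        "p_chr4": float(tests.loc["chr4", "p_wilcoxon"]),
        "p_control": float(tests.loc["euchromatin", "p_wilcoxon"]),
    }
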