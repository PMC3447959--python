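"""RNA polymerase II pausing statistics.

Two pausing-index definitions are implemented:

* ``groseq``: PI = read density in the first 500 bp from the TSS divided by
  the density over the first 25% of the remaining gene length, on the gene's
  strand. Threshold 10 by convention.
* ``chip``: PI = maximum Pol II enrichment in a TSS +/- 300 bp window over
  the median enrichment across the gene body (600 bp downstream of the TSS
  to the gene end), computed on linear-scale intensities (2^M) by default.
  Threshold 4 by convention.

Genes shorter than 500 bp and genes overlapping any other gene are excluded
before either statistic; a 0/0 GRO-seq ratio marks the gene as not
polymerase-associated and drops it from paused-fraction denominators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    DomainPartition,
    GeneModel,
    ProbeTrack,
    ReadDensityTrack,
)

log = logging.getLogger(__name__)

GROSEQ_THRESHOLD = 10.0
CHIP_THRESHOLD = 4.0
FIVE_PRIME_BP = 500
CHIP_TSS_WINDOW = 300
CHIP_BODY_OFFSET = 600


@dataclass
class PausingResult:
    gene_id: str
    pi: float | None          # None = undefined (0/0, not polymerase-associated)
    method: str               # "groseq" | "chip"
    paused: bool
    threshold: float
    domain: str = ""

    @property
    def associated(self) -> bool:
        return self.pi is not None


def filter_genes_for_pi(genes: list[GeneModel]) -> list[GeneModel]:
    """Eligible genes: >= 500 bp and not overlapping any other gene (any bp,
    either strand)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    keep: list[GeneModel] = []
    for glist in by_chrom.values():
        glist = sorted(glist, key=lambda g: (g.interval.start, g.interval.end))
        bad: set[str] = set()
        max_end = -1
        max_owner = None
        for g in glist:
            if g.interval.start < max_end:
                bad.add(g.gene_id)
                bad.add(max_owner)
            if g.interval.end > max_end:
                max_end = g.interval.end
                max_owner = g.gene_id
        keep.extend(
            g for g in glist if g.length >= FIVE_PRIME_BP and g.gene_id not in bad
        )
    keep.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return keep


def _oriented_windows(gene: GeneModel) -> tuple[tuple[int, int], tuple[int, int]]:
    """(first 500 bp, next ceil(0.25*(L-500)) bp) as genomic [start, end)."""
    L = gene.length
    body_len = math.ceil(0.25 * (L - FIVE_PRIME_BP))
    if gene.oriented_forward:
        s = gene.interval.start
        five = (s, s + FIVE_PRIME_BP)
        body = (s + FIVE_PRIME_BP, s + FIVE_PRIME_BP + body_len)
    else:
        e = gene.interval.end
        five = (e - FIVE_PRIME_BP, e)
        body = (e - FIVE_PRIME_BP - body_len, e - FIVE_PRIME_BP)
    return five, body


def pi_groseq(density: ReadDensityTrack, gene: GeneModel) -> float | None:
    """GRO-seq pausing index; None when both windows are empty (0/0)."""
    if gene.length <= FIVE_PRIME_BP:
        raise ValueError(f"{gene.gene_id}: gene length must exceed {FIVE_PRIME_BP} bp")
    if gene.interval.end > density.chrom_lengths.get(gene.chrom, gene.interval.end):
        raise ValueError(f"{gene.gene_id}: gene extends past chrom end")
    strand = "+" if gene.oriented_forward else "-"
    (f_lo, f_hi), (b_lo, b_hi) = _oriented_windows(gene)
    five = density.window_sum(gene.chrom, strand, f_lo, f_hi) / (f_hi - f_lo)
    body = density.window_sum(gene.chrom, strand, b_lo, b_hi) / (b_hi - b_lo)
    if body == 0.0:
        return math.inf if five > 0 else None
    return five / body


def pi_chip(
    track: ProbeTrack, gene: GeneModel, scale: str = "linear"
) -> float | None:
    """ChIP pausing index: max(TSS +/- 300 bp) / median(body) of Pol II signal.

    ``scale='linear'`` (default) exponentiates M-values (2^M) before the
    ratio so the statistic stays positive; ``scale='log'`` ratios raw
    M-values. Returns None (gene skipped, logged) when the windows lack the
    minimum probe support (>=1 TSS probe, >=2 body probes).
    """
    if gene.chrom not in track.data:
        return None
    tss_vals = track.slice_values(
        gene.chrom, gene.tss - CHIP_TSS_WINDOW, gene.tss + CHIP_TSS_WINDOW + 1
    )
    if gene.oriented_forward:
        body_lo, body_hi = gene.tss + CHIP_BODY_OFFSET, gene.interval.end
    else:
        body_lo, body_hi = gene.interval.start, gene.tss - CHIP_BODY_OFFSET + 1
    body_vals = track.slice_values(gene.chrom, body_lo, body_hi)
    if tss_vals.size < 1 or body_vals.size < 2:
        log.info("pi_chip: skipping %s (insufficient probes)", gene.gene_id)
        return None
    if scale == "linear":
        return float(2 ** tss_vals.max() / np.median(2.0 ** body_vals))
    denom = float(np.median(body_vals))
    if denom == 0.0:
        return math.inf if tss_vals.max() > 0 else None
    return float(tss_vals.max() / denom)


def compute_pausing(
    genes: list[GeneModel],
    partition: DomainPartition,
    method: str,
    density: ReadDensityTrack | None = None,
    track: ProbeTrack | None = None,
    threshold: float | None = None,
    prefilter: bool = True,
) -> list[PausingResult]:
    """Per-gene pausing results for one method over eligible genes."""
    if method == "groseq":
        threshold = GROSEQ_THRESHOLD if threshold is None else threshold
    elif method == "chip":
        threshold = CHIP_THRESHOLD if threshold is None else threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    eligible = filter_genes_for_pi(genes) if prefilter else genes
    out = []
    for g in eligible:
        pi = pi_groseq(density, g) if method == "groseq" else pi_chip(track, g)
        out.append(
            PausingResult(
                gene_id=g.gene_id,
                pi=pi,
                method=method,
                paused=(pi is not None and pi > threshold),
                threshold=threshold,
                domain=partition.label_of_gene(g),
            )
        )
    return out


def paused_fraction(
    results: list[PausingResult],
    threshold: float | None = None,
) -> dict[str, tuple[int, float]]:
    """Per-domain (n polymerase-associated, fraction paused at threshold).

    The denominator is genes with a defined PI; undefined (0/0) genes are
    not polymerase-associated and are excluded.
    """
    methods = {r.method for r in results}
    if len(methods) > 1:
        raise ValueError("mixed methods in one paused_fraction call")
    out: dict[str, tuple[int, float]] = {}
    for dom in sorted({r.domain for r in results}):
        assoc = [r for r in results if r.domain == dom and r.associated]
        if not assoc:
            continue
        thr = results[0].threshold if threshold is None else threshold
        n_paused = sum(1 for r in assoc if r.pi > thr)
        out[dom] = (len(assoc), n_paused / len(assoc))
    return out


def paused_fraction_sweep(
    results: list[PausingResult], thresholds: list[float]
) -> dict[float, dict[str, tuple[int, float]]]:
    """Threshold sweep for Fig-4B-style curves."""
    return {t: paused_fraction(results, threshold=t) for t in thresholds}


def pausing_domain_test(
    results: list[PausingResult],
    domain_a: str,
    domain_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float | None = None,
) -> tuple[float, float]:
    """Two-sided permutation test of paused-fraction difference between two
    domains: null shuffles domain labels over polymerase-associated genes;
    p = (1 + #{|null| >= |obs|}) / (1 + n_perm). Returns (observed stat, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    assoc = [r for r in results if r.associated and r.domain in (domain_a, domain_b)]
    thr = (results[0].threshold if results else 0.0) if threshold is None else threshold
    flags = np.array([r.pi > thr for r in assoc], dtype=float)
    is_a = np.array([r.domain == domain_a for r in assoc])
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    if min(n_a, n_b) < 5:
        log.warning("pausing_domain_test: a domain has <5 associated genes")
    if n_a == 0 or n_b == 0:
        raise ValueError("both domains need at least one associated gene")
    obs = flags[is_a].mean() - flags[~is_a].mean()
    rng = np.random.default_rng(seed)
    total = flags.sum()
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_a = flags[rng.permutation(flags.size)[:n_a]].sum()
        null[i] = perm_a / n_a - (total - perm_a) / n_b
    p = (1.0 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (1.0 + n_perm)
    return float(obs), float(p)


def pi_ratio_mutant(
    wt: list[PausingResult], mut: list[PausingResult]
) -> tuple[dict[str, float], int, int]:
    """Per-gene PI_mut / PI_wt plus the count of genes with ratio > 1.

    Genes with undefined or infinite PI in either condition are excluded
    (and counted). Returns (ratios, n_increased, n_excluded).
    """
    wt_by = {r.gene_id: r for r in wt}
    mut_by = {r.gene_id: r for r in mut}
    common = sorted(set(wt_by) & set(mut_by))
    if not common:
        raise ValueError("no genes shared between conditions")
    ratios: dict[str, float] = {}
    excluded = 0
    for gid in common:
        a, b = wt_by[gid], mut_by[gid]
        if (
            a.pi is None or b.pi is None
            or not math.isfinite(a.pi) or not math.isfinite(b.pi)
            or a.pi == 0
        ):
            excluded += 1
            log.info("pi_ratio_mutant: excluding %s (undefined PI)", gid)
            continue
        ratios[gid] = b.pi / a.pi
    n_up = sum(1 for v in ratios.values() if v > 1.0)
    return ratios, n_up, excluded


def tss_peak_position(
    track: ProbeTrack, gene: GeneModel, window: int = 500
) -> tuple[int, bool] | None:
    """Strand-oriented offset (bp) of the maximal probe in TSS +/- window.

    Ties take the smallest offset. Returns (offset, low_confidence) where
    low_confidence flags a flat window; None when <3 probes fall in the
    window.
    """
    if gene.chrom not in track.data:
        return None
    pos, val = track.slice_probes(gene.chrom, gene.tss - window,
                                  gene.tss + window + 1)
    if pos.size < 3:
        return None
    offsets = (pos - gene.tss) if gene.oriented_forward else (gene.tss - pos)
    order = np.argsort(offsets, kind="stable")
    offsets, val = offsets[order], val[order]
    best = int(offsets[int(np.argmax(val))])  # argmax takes first (smallest offset)
    flat = bool(np.all(val == val[0]))
    return best, flat


def peak_shift(
    wt_track: ProbeTrack,
    mut_track: ProbeTrack,
    genes: list[GeneModel],
    window: int = 500,
) -> float:
    """mean(mutant TSS-peak offsets) - mean(WT offsets) over shared genes."""
    wt_off, mut_off = [], []
    for g in genes:
        a = tss_peak_position(wt_track, g, window)
        b = tss_peak_position(mut_track, g, window)
        if a is None or b is None:
            continue
        wt_off.append(a[0])
        mut_off.append(b[0])
    if not wt_off:
        raise ValueError("no genes with usable TSS windows")
    return float(np.mean(mut_off) - np.mean(wt_off))


def method_overlap(
    groseq: list[PausingResult],
    chip: list[PausingResult],
    top_n: list[int],
) -> dict[int, float]:
    """|top-N(groseq) ∩ top-N(chip)| / N for each N.

    Transcript-level GRO-seq results are reduced to gene level by max PI.
    Undefined PIs rank last; ties break by gene id for determinism.
    """
    def ranked(results: list[PausingResult]) -> list[str]:
        best: dict[str, float] = {}
        for r in results:
            v = -math.inf if r.pi is None else r.pi
            best[r.gene_id] = max(best.get(r.gene_id, -math.inf), v)
        return [g for g, _ in sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))]

    ra, rb = ranked(groseq), ranked(chip)
    out = {}
    for n in top_n:
        n_eff = min(n, len(ra), len(rb))
        if n_eff < n:
            log.warning("method_overlap: N=%d capped to %d", n, n_eff)
        out[n] = len(set(ra[:n_eff]) & set(rb[:n_eff])) / n_eff
    return out
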