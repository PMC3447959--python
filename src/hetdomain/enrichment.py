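"""Track-level enrichment computation.

Smoothing, enrichment-region calling against a robust Gaussian null with
step-up FDR control, replicate consistency checks, fixed-width binning,
per-domain mark correlations, and the two cross-condition normalizations
(MAD-of-lagged-differences scaling and quantile normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    DomainPartition,
    EnrichedRegion,
    EnrichedRegionSet,
    GenomicInterval,
    ProbeTrack,
    ValidationError,
)


# ---------------------------------------------------------------------------
# smoothing


def smooth_track(track: ProbeTrack, window_bp: int = 500) -> ProbeTrack:
    """Centered moving average: each probe becomes the mean of probes within
    +/- window_bp/2 of its position. The probe set is unchanged; constants
    are preserved and the operator is shift-equivariant."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp / 2.0
    new = {}
    for chrom in track.chroms:
        pos, val = track.data[chrom]
        if pos.size == 0:
            new[chrom] = val.copy()
            continue
        csum = np.concatenate([[0.0], np.cumsum(val)])
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        new[chrom] = (csum[hi] - csum[lo]) / (hi - lo)
    return track.with_values(new)


# ---------------------------------------------------------------------------
# region calling


def _half_sample_mode(x: np.ndarray) -> float:
    """Robust mode by recursive half-sample (shorth) search."""
    x = np.sort(np.asarray(x, float))
    while x.size > 3:
        h = x.size // 2
        widths = x[h:] - x[: x.size - h]
        i = int(np.argmin(widths))
        x = x[i: i + h + 1]
    return float(np.mean(x))


def fit_null(values: np.ndarray) -> tuple[float, float]:
    """Gaussian null (mu, sigma) fitted to the mode-centered bulk.

    mu = half-sample mode; sigma from the median absolute deviation of the
    lower half (values below the mode), immune to the enriched right tail.
    """
    values = np.asarray(values, float)
    mu = _half_sample_mode(values)
    below = mu - values[values < mu]
    if below.size < 3:
        return mu, 0.0
    sigma = float(np.median(below)) / 0.6744897501960817
    return mu, sigma


def call_enriched_regions(
    track: ProbeTrack,
    fdr: float = 1e-3,
    merge_gap: int = 1000,
    min_probes: int = 3,
) -> EnrichedRegionSet:
    """Call significantly enriched regions on a smoothed track.

    One-sided per-probe p-values against the robust Gaussian null,
    Benjamini-Hochberg step-up control at ``fdr``, significant probes within
    ``merge_gap`` bp joined, regions with fewer than ``min_probes``
    significant probes dropped. Region score = mean smoothed M.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must be in (0,1)")
    if track.n_probes < 10:
        raise ValidationError("track too small to fit a null (<10 probes)")
    values = track.all_values()
    mu, sigma = fit_null(values)
    if sigma == 0.0:
        return EnrichedRegionSet([], fdr)  # degenerate null: nothing callable
    pvals = stats.norm.sf(values, loc=mu, scale=sigma)
    reject = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]

    regions: list[EnrichedRegion] = []
    offset = 0
    for chrom in track.chroms:
        pos, val = track.data[chrom]
        rej = reject[offset: offset + pos.size]
        offset += pos.size
        sig_idx = np.flatnonzero(rej)
        if sig_idx.size == 0:
            continue
        sig_pos = pos[sig_idx]
        breaks = np.flatnonzero(np.diff(sig_pos) > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [sig_idx.size - 1]])
        for s, e in zip(starts, ends):
            n = e - s + 1
            if n < min_probes:
                continue
            lo, hi = int(sig_pos[s]), int(sig_pos[e]) + 1
            score = float(val[sig_idx[s]: sig_idx[e] + 1].mean())
            regions.append(
                EnrichedRegion(GenomicInterval(chrom, lo, hi), score, n_probes=n)
            )
    return EnrichedRegionSet(regions, fdr)


# ---------------------------------------------------------------------------
# replicate consistency


@dataclass
class ConsistencyReport:
    passed: bool
    target_overlap: float        # symmetric fraction of targets shared
    top40_overlap: float         # same, on the top 40% of targets by score
    reason: str = ""


def _match_fraction(a: list[EnrichedRegion], b: list[EnrichedRegion],
                    by_bp: bool = False) -> float:
    """Symmetric overlap fraction between two target lists.

    Target-count based by default (fraction of regions in either list that
    overlap a region of the other); base-pair based behind ``by_bp``.
    """
    if not a or not b:
        return 0.0
    if by_bp:
        bp_a = sum(len(r.interval) for r in a)
        bp_b = sum(len(r.interval) for r in b)
        shared = 0
        for ra in a:
            for rb in b:
                if ra.interval.overlaps(rb.interval):
                    shared += min(ra.interval.end, rb.interval.end) - max(
                        ra.interval.start, rb.interval.start
                    )
        return 2.0 * shared / (bp_a + bp_b)
    hit_a = sum(1 for ra in a if any(ra.interval.overlaps(rb.interval) for rb in b))
    hit_b = sum(1 for rb in b if any(rb.interval.overlaps(ra.interval) for ra in a))
    return (hit_a + hit_b) / (len(a) + len(b))


def replicate_consistency(
    a: EnrichedRegionSet, b: EnrichedRegionSet, by_bp: bool = False
) -> ConsistencyReport:
    """Replicates are consistent if target lists overlap by more than 75%,
    or if the top 40% of targets by score share more than 80%."""
    if len(a) == 0 or len(b) == 0:
        return ConsistencyReport(False, 0.0, 0.0, "empty replicate target list")
    overlap = _match_fraction(a.regions, b.regions, by_bp)
    top_a = sorted(a.regions, key=lambda r: -r.score)[: max(1, int(0.4 * len(a)))]
    top_b = sorted(b.regions, key=lambda r: -r.score)[: max(1, int(0.4 * len(b)))]
    top40 = _match_fraction(top_a, top_b, by_bp)
    passed = overlap > 0.75 or top40 > 0.80
    return ConsistencyReport(passed, overlap, top40,
                             "" if passed else "below both consistency rules")


# ---------------------------------------------------------------------------
# binning and correlation


@dataclass
class BinMatrix:
    """Fixed-width genomic bins x marks matrix of mean M (NaN = empty bin)."""

    bins: list[GenomicInterval]
    matrix: pd.DataFrame  # rows align with bins, columns are mark names
    width: int

    def __post_init__(self):
        if len(self.bins) != len(self.matrix):
            raise ValidationError("bin count does not match matrix rows")


def bin_enrichment(
    tracks: list[ProbeTrack],
    width: int = 500,
    chrom_lengths: dict[str, int] | None = None,
) -> BinMatrix:
    """Tile each chrom with ``width``-bp bins; cell = mean M of probes in bin."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    if not tracks:
        raise ValueError("no tracks")
    if chrom_lengths is None:
        chrom_lengths = {}
        for t in tracks:
            for chrom in t.chroms:
                pos = t.positions(chrom)
                if pos.size:
                    chrom_lengths[chrom] = max(
                        chrom_lengths.get(chrom, 0), int(pos[-1]) + 1
                    )
    bins: list[GenomicInterval] = []
    per_chrom_nbins = {}
    for chrom in sorted(chrom_lengths):
        n = -(-chrom_lengths[chrom] // width)
        per_chrom_nbins[chrom] = (len(bins), n)
        bins.extend(
            GenomicInterval(chrom, i * width, min((i + 1) * width,
                                                  chrom_lengths[chrom]))
            for i in range(n)
        )
    cols = {}
    for t in tracks:
        col = np.full(len(bins), np.nan)
        for chrom, (start_row, n) in per_chrom_nbins.items():
            if chrom not in t.data:
                continue
            pos, val = t.data[chrom]
            idx = pos // width
            ok = idx < n
            sums = np.bincount(idx[ok], weights=val[ok], minlength=n)
            counts = np.bincount(idx[ok], minlength=n)
            with np.errstate(invalid="ignore"):
                col[start_row: start_row + n] = np.where(
                    counts > 0, sums / np.maximum(counts, 1), np.nan
                )
        name = t.mark if t.mark not in cols else f"{t.mark}/{t.condition}"
        cols[name] = col
    return BinMatrix(bins=bins, matrix=pd.DataFrame(cols), width=width)


def mark_correlation(
    bm: BinMatrix, domain: str, partition: DomainPartition
) -> pd.DataFrame:
    """Pearson correlation between marks over complete bins inside a domain."""
    if bm.matrix.shape[1] < 2:
        raise ValueError("need at least two marks")
    regions = partition.regions_for(domain)
    mask = np.zeros(len(bm.bins), bool)
    for i, b in enumerate(bm.bins):
        for iv in regions:
            if iv.chrom == b.chrom and iv.start <= b.start and b.end <= iv.end:
                mask[i] = True
                break
    sub = bm.matrix[mask].dropna()
    if len(sub) < 10:
        raise ValidationError(f"fewer than 10 complete bins in domain {domain!r}")
    corr = sub.corr()  # pairwise Pearson; zero-variance marks yield NaN, flagged
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ---------------------------------------------------------------------------
# cross-condition normalizations


@dataclass
class NormalizationFactor:
    value: float
    wt_mad: float
    mut_mad: float


def _lagged_mad(track: ProbeTrack) -> float:
    """median |d_i - median(d_i)| of within-chrom lagged probe differences."""
    diffs = []
    for chrom in track.chroms:
        val = track.values(chrom)
        if val.size >= 2:
            diffs.append(np.diff(val))
    if not diffs:
        raise ValidationError("track too short for lagged differences")
    d = np.concatenate(diffs)
    return float(np.median(np.abs(d - np.median(d))))


def scale_mutant_to_wt(
    wt: ProbeTrack, mut: ProbeTrack
) -> tuple[NormalizationFactor, ProbeTrack]:
    """Noise-level scaling of a mutant track onto the wildtype.

    factor = MAD(lagged diffs of WT) / MAD(lagged diffs of mutant); the
    rescaled track is mutant M-values x factor. Additive offsets cancel in
    the lagged differences, and a pure multiplicative distortion is inverted
    exactly.
    """
    if not wt.same_grid(mut):
        raise ValidationError("WT and mutant tracks are on different probe grids")
    wt_mad = _lagged_mad(wt)
    mut_mad = _lagged_mad(mut)
    if mut_mad == 0.0:
        raise ValidationError("degenerate mutant track (zero MAD of differences)")
    factor = wt_mad / mut_mad
    rescaled = mut.with_values(
        {c: mut.values(c) * factor for c in mut.chroms}
    )
    return NormalizationFactor(factor, wt_mad, mut_mad), rescaled


def quantile_normalize(tracks: list[ProbeTrack]) -> list[ProbeTrack]:
    """Quantile normalization across tracks on a shared grid.

    Reference distribution = mean of the sorted value vectors; ties within a
    track receive the average of the reference values over the tied ranks,
    so rank order is preserved and output sorted vectors are identical.
    """
    if not tracks:
        return []
    lengths = {t.n_probes for t in tracks}
    if len(lengths) != 1:
        raise ValidationError("quantile normalization needs equal probe counts")
    n = lengths.pop()
    stacked = np.stack([t.all_values() for t in tracks])
    reference = np.sort(stacked, axis=1).mean(axis=0)

    out = []
    for t, row in zip(tracks, stacked):
        order = np.argsort(row, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # average reference values over tied ranks
        sorted_vals = row[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0)
        starts = np.concatenate([[0], boundaries + 1])
        ends = np.concatenate([boundaries + 1, [n]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        new = {}
        offset = 0
        for chrom in t.chroms:
            size = t.positions(chrom).size
            new[chrom] = assigned[offset: offset + size]
            offset += size
        out.append(t.with_values(new))
    return out
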