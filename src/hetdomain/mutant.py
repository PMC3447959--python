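"""Mutant-vs-wildtype comparative analyses.

Peak retention under the mutant's own enrichment call, level/extent change
summaries by feature class and domain, a distance-to-nearest-repeat
permutation test for residual peaks, paired expression contrasts, and
correlation of pausing-index changes with wildtype mark enrichment.

All comparisons assume the mutant track has been rescaled with
``enrichment.scale_mutant_to_wt``, which makes them invariant to a
multiplicative distortion of the raw mutant data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DomainPartition,
    EnrichedRegionSet,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    ProbeTrack,
)
from .enrichment import call_enriched_regions
from .metagene import feature_class_means

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# peak retention


def peak_retention(
    wt_regions: EnrichedRegionSet,
    mut_track: ProbeTrack,
    fdr: float | None = None,
    n_score_bins: int = 4,
    **caller_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Fraction of WT peaks reduced in the mutant, with per-peak flags.

    A WT peak is "reduced" when no mutant enriched region (called at the
    same FDR on the rescaled mutant track) covers at least 50% of it.
    Also reports the reduced fraction binned by WT peak M-value.
    """
    if len(wt_regions) == 0:
        raise ValueError("empty wildtype region set")
    fdr = wt_regions.fdr_threshold if fdr is None else fdr
    mut_regions = call_enriched_regions(mut_track, fdr=fdr, **caller_kwargs)
    rows = []
    for r in wt_regions:
        covered = 0
        for m in mut_regions:
            if m.interval.overlaps(r.interval):
                covered += min(m.interval.end, r.interval.end) - max(
                    m.interval.start, r.interval.start
                )
        reduced = covered < 0.5 * len(r.interval)
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "wt_score": r.score,
                "covered_frac": covered / len(r.interval),
                "reduced": reduced,
            }
        )
    table = pd.DataFrame(rows)
    try:
        table["score_bin"] = pd.qcut(table["wt_score"], n_score_bins,
                                     duplicates="drop")
    except ValueError:
        table["score_bin"] = "all"
    return float(table["reduced"].mean()), table


# ---------------------------------------------------------------------------
# change summaries


@dataclass
class ChangeSummary:
    level: pd.DataFrame   # (domain, feature_class) x [wt_mean, mut_mean, pct_change]
    extent: pd.DataFrame  # domain x [wt_bp, mut_bp, wt_regions, mut_regions, pct_change]


def _pct_change(wt: float, mut: float) -> float:
    if wt > 0:
        return 100.0 * (1.0 - mut / wt)
    return float("nan")  # flagged undefined when the WT mean is non-positive


def enrichment_change_summary(
    wt_track: ProbeTrack,
    mut_track_rescaled: ProbeTrack,
    partition: DomainPartition,
    genes: list[GeneModel],
    active: dict[str, bool],
    fdr: float = 1e-3,
    **caller_kwargs,
) -> ChangeSummary:
    """Level change from feature-class means and extent change from
    enriched-bp totals at the calling FDR, per domain."""
    wt_means = feature_class_means(wt_track, genes, partition, active)
    mut_means = feature_class_means(mut_track_rescaled, genes, partition, active)
    joined = wt_means.join(mut_means, lsuffix="_wt", rsuffix="_mut", how="outer")
    level = pd.DataFrame(
        {
            "wt_mean": joined["mean_wt"],
            "mut_mean": joined["mean_mut"],
            "pct_change": [
                _pct_change(w, m)
                for w, m in zip(joined["mean_wt"], joined["mean_mut"])
            ],
        }
    )

    wt_regions = call_enriched_regions(wt_track, fdr=fdr, **caller_kwargs)
    mut_regions = call_enriched_regions(mut_track_rescaled, fdr=fdr, **caller_kwargs)
    rows = {}
    for dom in partition.labels():
        ivs = partition.regions_for(dom)
        wt_bp = wt_regions.total_bp(ivs)
        mut_bp = mut_regions.total_bp(ivs)
        rows[dom] = {
            "wt_bp": wt_bp,
            "mut_bp": mut_bp,
            "wt_regions": sum(
                1 for r in wt_regions if any(r.interval.overlaps(iv) for iv in ivs)
            ),
            "mut_regions": sum(
                1 for r in mut_regions if any(r.interval.overlaps(iv) for iv in ivs)
            ),
            "pct_change": _pct_change(wt_bp, mut_bp),
        }
    return ChangeSummary(level=level, extent=pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# distance to repeats


def _nearest_repeat_distances(
    starts: np.ndarray, ends: np.ndarray, repeats: list[GenomicInterval]
) -> np.ndarray:
    """bp gap from each [start, end) peak to its nearest repeat (0 if they
    overlap); repeats must all be on the peak's chromosome."""
    r_starts = np.array([r.start for r in repeats])
    r_ends = np.array([r.end for r in repeats])
    order = np.argsort(r_starts)
    r_starts, r_ends = r_starts[order], r_ends[order]
    out = np.empty(starts.size, dtype=np.int64)
    for i, (s, e) in enumerate(zip(starts, ends)):
        # gap to each repeat; negative or zero means overlap
        gaps = np.maximum(r_starts - e, s - r_ends)
        out[i] = max(0, int(gaps.min()))
    return out


def _random_placements(
    rng: np.random.Generator, lengths: np.ndarray, dom_start: int, dom_end: int
) -> np.ndarray:
    """Non-overlapping uniform placement of peaks of given lengths within the
    domain, preserving count and lengths (order randomized)."""
    lengths = rng.permutation(lengths)
    free = (dom_end - dom_start) - int(lengths.sum())
    if free < 0:
        raise ValueError("peaks do not fit in the domain")
    gaps = np.sort(rng.integers(0, free + 1, size=lengths.size))
    gaps = np.diff(np.concatenate([[0], gaps]))
    starts = dom_start + np.cumsum(gaps) + np.concatenate(
        [[0], np.cumsum(lengths[:-1])]
    )
    return starts, lengths


def distance_to_repeat_test(
    peaks: EnrichedRegionSet,
    repeats: list[GenomicInterval],
    domain: GenomicInterval,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Observed median peak-to-nearest-repeat distance vs a uniform-placement
    null. Null placements preserve peak count and lengths, never overlap each
    other, and stay within the domain. One-sided
    p = (1 + #{null median <= observed}) / (1 + n_perm).
    Returns (observed_median, expected_median, p).
    """
    dom_repeats = [r for r in repeats if r.overlaps(domain)]
    if not dom_repeats:
        raise ValueError("no repeats in the domain")
    dom_peaks = [r for r in peaks if r.interval.overlaps(domain)]
    if not dom_peaks:
        raise ValueError("no peaks in the domain")
    starts = np.array([r.interval.start for r in dom_peaks])
    ends = np.array([r.interval.end for r in dom_peaks])
    observed = float(np.median(_nearest_repeat_distances(starts, ends, dom_repeats)))

    lengths = ends - starts
    rng = np.random.default_rng(seed)
    null_medians = np.empty(n_perm)
    for i in range(n_perm):
        s, ln = _random_placements(rng, lengths, domain.start, domain.end)
        null_medians[i] = np.median(_nearest_repeat_distances(s, s + ln, dom_repeats))
    p = (1.0 + np.sum(null_medians <= observed)) / (1.0 + n_perm)
    return observed, float(null_medians.mean()), float(p)


# ---------------------------------------------------------------------------
# expression contrasts


def expression_change(
    wt: ExpressionTable,
    mut: ExpressionTable,
    partition_of: dict[str, str],
    gene_set: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 fold change (pseudocount 1) and per-group paired
    Wilcoxon signed-rank tests with decreased/increased counts.

    Groups are domains from ``partition_of`` (gene_id -> label), or the
    single supplied ``gene_set``. Zero-difference pairs are dropped by the
    signed-rank test; a group with no nonzero differences reports p = 1.
    Groups with fewer than 6 paired genes are flagged unreliable.
    """
    common = sorted(set(wt.values) & set(mut.values))
    if not common:
        raise ValueError("no genes shared between tables")
    fc = pd.DataFrame(
        {
            "gene_id": common,
            "wt": [wt[g] for g in common],
            "mut": [mut[g] for g in common],
        }
    )
    fc["log2_fc"] = np.log2((fc["mut"] + 1.0) / (fc["wt"] + 1.0))
    if gene_set is not None:
        fc["group"] = np.where(fc["gene_id"].isin(set(gene_set)), "gene_set", "rest")
    else:
        fc["group"] = [partition_of.get(g, "unassigned") for g in common]

    rows = {}
    for grp, sub in fc.groupby("group"):
        diffs = sub["mut"].to_numpy() - sub["wt"].to_numpy()
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            p = 1.0
        else:
            p = float(stats.wilcoxon(nonzero, alternative="two-sided").pvalue)
        rows[grp] = {
            "n": len(sub),
            "n_decreased": int((diffs < 0).sum()),
            "n_increased": int((diffs > 0).sum()),
            "p_wilcoxon": p,
            "unreliable": len(sub) < 6,
        }
    return fc, pd.DataFrame.from_dict(rows, orient="index")


def pi_change_correlation(
    pi_ratios: dict[str, float],
    mark_enrichment: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Pearson r between per-gene PI change and WT mark enrichment.

    ``mark_enrichment`` maps mark -> gene_id -> mean M. Genes are matched by
    id; marks with zero variance report a missing entry. Rows are ordered by
    PI ratio for heatmap export.
    """
    rows = {}
    gene_order = sorted(pi_ratios, key=lambda g: -pi_ratios[g])
    for mark, values in sorted(mark_enrichment.items()):
        common = [g for g in gene_order if g in values]
        if len(common) < 10:
            raise ValueError(f"mark {mark}: fewer than 10 matched genes")
        x = np.array([pi_ratios[g] for g in common])
        y = np.array([values[g] for g in common])
        if np.std(x) == 0 or np.std(y) == 0:
            rows[mark] = {"r": float("nan"), "n": len(common)}
            continue
        rows[mark] = {"r": float(stats.pearsonr(x, y)[0]), "n": len(common)}
    return pd.DataFrame.from_dict(rows, orient="index")
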