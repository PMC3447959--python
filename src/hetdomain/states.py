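"""Combinatorial chromatin-state assignment over binned multi-mark signal.

K-means with a generous initial k, followed by iterative merging of clusters
whose centroid profiles are highly correlated, mirrors the usual practice of
over-clustering and collapsing redundant states. Final states are renamed
A, B, C, ... in order of decreasing silencing-mark centroid weight, so label
semantics are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import DomainPartition, GeneModel, GenomicInterval, ValidationError
from .enrichment import BinMatrix

SILENCING_MARK_HINTS = ("H3K9", "HP1")

FEATURE_CLASSES = ("tss", "exon", "intron", "intergenic")


@dataclass
class StateAssignment:
    bins: list[GenomicInterval]          # complete bins only
    labels: list[str]                    # per-bin final state name (A, B, ...)
    centroids: pd.DataFrame              # rows = state names, cols = marks (z units)
    k_initial: int
    k_final: int

    def __post_init__(self):
        if len(self.bins) != len(self.labels):
            raise ValidationError("labels do not match bins")
        if self.k_final > self.k_initial:
            raise ValidationError("k_final exceeds k_initial")


def _split_ratio(X: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Centroid separation over pooled within-cluster spread, both measured
    along the axis joining the two centroids (a two-means split statistic)."""
    ca, cb = X[a].mean(axis=0), X[b].mean(axis=0)
    v = ca - cb
    d = float(np.linalg.norm(v))
    if d == 0.0:
        return 0.0
    v = v / d
    pa, pb = X[a] @ v, X[b] @ v
    pooled = np.sqrt(
        (pa.var() * pa.size + pb.var() * pb.size) / (pa.size + pb.size)
    )
    return d / pooled if pooled > 0 else np.inf


def _merge_similar(
    assignments: np.ndarray, X: np.ndarray, threshold: float,
    split_ratio_cut: float,
) -> np.ndarray:
    """Iteratively merge cluster pairs with similar enrichment patterns.

    Two clusters merge when their centroid Pearson correlation exceeds
    ``threshold`` (same combinatorial signature), or when their split ratio
    (centroid separation / projected within-cluster spread) falls below
    ``split_ratio_cut`` — fragments of one homogeneous population are not
    separated beyond their own noise, and without the second rule they could
    never collapse: complementary K-means fragments have anti-correlated
    centroids. The least-separated pair merges first; everything is
    recomputed after each merge.
    """
    labels = assignments.copy()
    while True:
        uniq = np.unique(labels)
        if uniq.size <= 1:
            break
        masks = [labels == u for u in uniq]
        cent = np.stack([X[m].mean(axis=0) for m in masks])
        if cent.shape[1] < 2:
            corr = np.full((uniq.size, uniq.size), -np.inf)
        else:
            corr = np.nan_to_num(np.corrcoef(cent), nan=-np.inf)
        np.fill_diagonal(corr, -np.inf)
        ratio = np.full((uniq.size, uniq.size), np.inf)
        for i in range(uniq.size):
            for j in range(i + 1, uniq.size):
                ratio[i, j] = ratio[j, i] = _split_ratio(X, masks[i], masks[j])
        if ratio.min() < split_ratio_cut:
            i, j = np.unravel_index(np.argmin(ratio), ratio.shape)
        elif corr.max() > threshold:
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
        else:
            break
        labels[labels == uniq[j]] = uniq[i]
    return labels


def fit_states(
    bm: BinMatrix,
    k_initial: int = 10,
    merge_threshold: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    silencing_marks: list[str] | None = None,
    split_ratio_cut: float = 4.0,
) -> StateAssignment:
    """Cluster complete bins into combinatorial chromatin states.

    Marks are z-scored, K-means is run with ``k_initial`` clusters and
    ``n_init`` restarts under a fixed seed, then clusters whose centroid
    Pearson correlation exceeds ``merge_threshold`` — or whose two-means split
    ratio falls below ``split_ratio_cut`` — are merged
    iteratively (most similar pair first). States are named A, B, ... by descending mean of
    the silencing-mark centroid components (marks matching H3K9*/HP1* by
    default, all marks if none match).
    """
    if k_initial < 2:
        raise ValueError("k_initial must be >= 2")
    complete = bm.matrix.notna().all(axis=1).to_numpy()
    if complete.sum() < k_initial:
        raise ValidationError(
            f"only {int(complete.sum())} complete bins for k_initial={k_initial}"
        )
    X = bm.matrix.to_numpy()[complete]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    km = KMeans(n_clusters=k_initial, n_init=n_init, random_state=seed)
    raw = km.fit_predict(Xz)
    merged = _merge_similar(raw, Xz, merge_threshold, split_ratio_cut)

    marks = list(bm.matrix.columns)
    if silencing_marks is None:
        silencing_marks = [
            m for m in marks if any(h in m for h in SILENCING_MARK_HINTS)
        ] or marks
    sil_idx = [marks.index(m) for m in silencing_marks]

    uniq = np.unique(merged)
    cent = np.stack([Xz[merged == u].mean(axis=0) for u in uniq])
    order = np.argsort(-cent[:, sil_idx].mean(axis=1), kind="stable")
    names = {uniq[order[i]]: chr(ord("A") + i) for i in range(uniq.size)}

    bins = [b for b, ok in zip(bm.bins, complete) if ok]
    labels = [names[u] for u in merged]
    centroids = pd.DataFrame(
        cent[order], index=[chr(ord("A") + i) for i in range(uniq.size)],
        columns=marks,
    )
    return StateAssignment(
        bins=bins, labels=labels, centroids=centroids,
        k_initial=k_initial, k_final=int(uniq.size),
    )


def state_chrom_enrichment(
    sa: StateAssignment, partition: DomainPartition
) -> pd.DataFrame:
    """Per-domain state fractions and fold-enrichment over genome-wide.

    fold = (state fraction in domain) / (state fraction overall); empty
    domains are reported as missing rows.
    """
    states = sorted(set(sa.labels))
    lab_arr = np.array(sa.labels)
    overall = {s: float(np.mean(lab_arr == s)) for s in states}
    rows = {}
    for dom in partition.labels():
        regions = partition.regions_for(dom)
        in_dom = np.array([
            any(iv.chrom == b.chrom and iv.start <= b.start and b.end <= iv.end
                for iv in regions)
            for b in sa.bins
        ])
        if not in_dom.any():
            continue
        frac = {s: float(np.mean(lab_arr[in_dom] == s)) for s in states}
        rows[dom] = {
            **{f"frac_{s}": frac[s] for s in states},
            **{
                f"fold_{s}": (frac[s] / overall[s]) if overall[s] > 0 else np.nan
                for s in states
            },
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def state_feature_association(
    sa: StateAssignment, genes: list[GeneModel], tss_flank: int = 500
) -> pd.DataFrame:
    """Per-state fractions over {tss, exon, intron, intergenic}.

    Each bin is assigned one feature class by majority base pairs, ties
    broken by priority tss > exon > intron > intergenic. Fractions sum to 1
    per state.
    """
    # paint per-chrom class codes; higher priority painted last
    chrom_len: dict[str, int] = {}
    for b in sa.bins:
        chrom_len[b.chrom] = max(chrom_len.get(b.chrom, 0), b.end)
    for g in genes:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.interval.end,
                                 g.tss + tss_flank)
    code = {c: np.full(n, 3, dtype=np.uint8) for c, n in chrom_len.items()}
    for g in genes:
        code[g.chrom][g.interval.start: g.interval.end] = 2  # intron default
    for g in genes:
        for ex in g.exons:
            code[ex.chrom][ex.start: ex.end] = 1
    for g in genes:
        lo = max(0, g.tss - tss_flank)
        hi = min(chrom_len[g.chrom], g.tss + tss_flank)
        code[g.chrom][lo:hi] = 0

    bin_class = []
    for b in sa.bins:
        counts = np.bincount(code[b.chrom][b.start: b.end], minlength=4)
        bin_class.append(FEATURE_CLASSES[int(np.argmax(counts))])  # tie -> priority
    bin_class = np.array(bin_class)

    lab_arr = np.array(sa.labels)
    rows = {}
    for s in sorted(set(sa.labels)):
        sel = bin_class[lab_arr == s]
        rows[s] = {c: float(np.mean(sel == c)) for c in FEATURE_CLASSES}
    return pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_CLASSES)]
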