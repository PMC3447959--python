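"""Expression classification and scaled metagene / heatmap profiles.

Gene bodies are rescaled onto a fixed 3-kb coordinate (60 bins of 50 bp by
default) with unscaled 2-kb flanks sampled at 50-bp steps; minus-strand
genes are reversed so every profile reads 5' to 3'. Mean and SEM are taken
across genes at each position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DomainPartition,
    ExpressionTable,
    GeneModel,
    ProbeTrack,
    ValidationError,
)

log = logging.getLogger(__name__)

RPKM_THRESHOLDS = {"cell_line": 0.6, "larvae": 0.4}  # on log10(RPKM+1)
FPKM_THRESHOLD_LOG2 = 1.4  # on log2(FPKM+1)


def classify_expressed(
    table: ExpressionTable, context: str = "cell_line"
) -> dict[str, bool]:
    """Active/silent call per gene.

    RPKM: active iff log10(RPKM+1) > 0.6 (cell lines) or 0.4 (larvae).
    FPKM: active iff log2(FPKM+1) > 1.4 (context-independent).
    """
    if table.unit == "RPKM":
        if context not in RPKM_THRESHOLDS:
            raise ValueError(f"unknown context {context!r}")
        thr = RPKM_THRESHOLDS[context]
        return {
            g: bool(np.log10(v + 1.0) > thr) for g, v in table.values.items()
        }
    return {
        g: bool(np.log2(v + 1.0) > FPKM_THRESHOLD_LOG2)
        for g, v in table.values.items()
    }


@dataclass
class MetageneProfile:
    positions: np.ndarray   # profile coordinate (bp; body section in scaled bp)
    mean: np.ndarray
    sem: np.ndarray
    n_genes: int
    flank_bins: int
    body_bins: int

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValidationError("profile over zero genes")
        if np.any(self.sem < 0):
            raise ValidationError("negative SEM")

    @property
    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.body_bins)

    @property
    def flank_index(self) -> np.ndarray:
        n = self.positions.size
        idx = np.zeros(n, bool)
        idx[: self.flank_bins] = True
        idx[self.flank_bins + self.body_bins:] = True
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "mean": self.mean, "sem": self.sem,
             "n": self.n_genes}
        )


def _fill_gaps(arr: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN bins (edges extended)."""
    nan = np.isnan(arr)
    if not nan.any():
        return arr
    if nan.all():
        return arr
    idx = np.arange(arr.size)
    arr = arr.copy()
    arr[nan] = np.interp(idx[nan], idx[~nan], arr[~nan])
    return arr


def _gene_profile(
    track: ProbeTrack,
    gene: GeneModel,
    flank_bp: int,
    flank_step: int,
    body_bins: int,
) -> np.ndarray | None:
    """One gene's profile row: upstream flank, scaled body, downstream flank."""
    chrom = gene.chrom
    if chrom not in track.data:
        return None
    start, end = gene.interval.start, gene.interval.end
    pos, val = track.slice_probes(chrom, start, end)
    if pos.size < 2:
        return None

    flank_bins = flank_bp // flank_step
    # scaled body: mean of probes per equal-width bin, gaps interpolated
    rel = (pos - start) / max(1, (end - start))
    bidx = np.minimum((rel * body_bins).astype(int), body_bins - 1)
    sums = np.bincount(bidx, weights=val, minlength=body_bins)
    counts = np.bincount(bidx, minlength=body_bins)
    body = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    body = _fill_gaps(body)

    def flank(lo: int) -> np.ndarray:
        fpos, fval = track.slice_probes(chrom, lo, lo + flank_bp)
        out = np.full(flank_bins, np.nan)
        if fpos.size:
            fi = np.minimum((fpos - lo) // flank_step, flank_bins - 1)
            s = np.bincount(fi, weights=fval, minlength=flank_bins)
            c = np.bincount(fi, minlength=flank_bins)
            out = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        return _fill_gaps(out)

    up = flank(start - flank_bp)
    down = flank(end)
    row = np.concatenate([up, body, down])
    if not gene.oriented_forward:
        row = row[::-1]
    if np.isnan(row).any():  # flanks entirely off-track
        return None
    return row


def metagene_profile(
    track: ProbeTrack,
    genes: list[GeneModel],
    flank_bp: int = 2000,
    flank_step: int = 50,
    body_bins: int = 60,
) -> MetageneProfile:
    """Average scaled-gene-body profile (3-kb-scaled body, +/-2 kb flanks).

    Genes whose bodies have fewer than 2 probes are skipped with a log
    message; SEM is across genes at each position (0 for a single gene).
    """
    if not genes:
        raise ValueError("no genes supplied")
    rows = []
    for g in genes:
        row = _gene_profile(track, g, flank_bp, flank_step, body_bins)
        if row is None:
            log.info("metagene: skipping %s (insufficient probes)", g.gene_id)
            continue
        rows.append(row)
    if not rows:
        raise ValidationError("all genes skipped (no usable probes)")
    mat = np.stack(rows)
    mean = mat.mean(axis=0)
    sem = (
        mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1
        else np.zeros(mat.shape[1])
    )
    flank_bins = flank_bp // flank_step
    body_scale = 3000
    positions = np.concatenate([
        np.arange(-flank_bp, 0, flank_step),
        np.linspace(0, body_scale, body_bins, endpoint=False),
        np.arange(body_scale, body_scale + flank_bp, flank_step),
    ])
    return MetageneProfile(
        positions=positions, mean=mean, sem=sem, n_genes=mat.shape[0],
        flank_bins=flank_bins, body_bins=body_bins,
    )


def metagene_heatmap(
    track: ProbeTrack,
    genes: list[GeneModel],
    anchor_bp: int = 500,
    anchor_step: int = 50,
    interior_bins: int = 40,
    min_length: int = 1000,
) -> pd.DataFrame:
    """Per-gene profile matrix: unscaled TSS/TES +/-500 bp anchors plus a
    scaled interior; genes shorter than ``min_length`` are excluded."""
    rows = {}
    anchor_bins = (2 * anchor_bp) // anchor_step
    for g in genes:
        if g.length < min_length:
            continue
        chrom = g.chrom
        if chrom not in track.data:
            continue

        def anchored(center: int) -> np.ndarray:
            lo = center - anchor_bp
            fpos, fval = track.slice_probes(chrom, lo, center + anchor_bp)
            out = np.full(anchor_bins, np.nan)
            if fpos.size:
                fi = np.minimum((fpos - lo) // anchor_step, anchor_bins - 1)
                s = np.bincount(fi, weights=fval, minlength=anchor_bins)
                c = np.bincount(fi, minlength=anchor_bins)
                out = np.where(c > 0, s / np.maximum(c, 1), np.nan)
            return _fill_gaps(out)

        fwd = g.oriented_forward
        left_anchor = g.interval.start
        right_anchor = g.interval.end
        in_lo, in_hi = left_anchor + anchor_bp, right_anchor - anchor_bp
        interior = np.full(interior_bins, np.nan)
        if in_hi > in_lo:
            ipos, ival = track.slice_probes(chrom, in_lo, in_hi)
            if ipos.size:
                rel = (ipos - in_lo) / (in_hi - in_lo)
                ii = np.minimum((rel * interior_bins).astype(int),
                                interior_bins - 1)
                s = np.bincount(ii, weights=ival, minlength=interior_bins)
                c = np.bincount(ii, minlength=interior_bins)
                interior = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        interior = _fill_gaps(interior)
        row = np.concatenate([anchored(left_anchor), interior,
                              anchored(right_anchor)])
        if not fwd:
            row = row[::-1]
        rows[g.gene_id] = row
    cols = (
        [f"tss{(i - anchor_bins // 2) * anchor_step:+d}" for i in range(anchor_bins)]
        + [f"body{i}" for i in range(interior_bins)]
        + [f"tes{(i - anchor_bins // 2) * anchor_step:+d}" for i in range(anchor_bins)]
    )
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def feature_class_means(
    track: ProbeTrack,
    genes: list[GeneModel],
    partition: DomainPartition,
    active: dict[str, bool],
    tss_flank: int = 500,
) -> pd.DataFrame:
    """Mean M +/- SEM for {active TSS, active gene body, silent region} per
    domain. Each gene contributes its probe-mean; SEM is across genes."""
    acc: dict[tuple[str, str], list[float]] = {}
    for g in genes:
        dom = partition.label_of_gene(g)
        if g.chrom not in track.data:
            continue
        if active.get(g.gene_id, False):
            tss_vals = track.slice_values(g.chrom, g.tss - tss_flank,
                                          g.tss + tss_flank)
            if g.oriented_forward:
                body_lo, body_hi = g.tss + tss_flank, g.interval.end
            else:
                body_lo, body_hi = g.interval.start, g.tss - tss_flank
            body_vals = track.slice_values(g.chrom, body_lo, body_hi)
            if tss_vals.size:
                acc.setdefault((dom, "active_tss"), []).append(float(tss_vals.mean()))
            if body_vals.size:
                acc.setdefault((dom, "active_body"), []).append(float(body_vals.mean()))
        else:
            vals = track.slice_values(g.chrom, g.interval.start, g.interval.end)
            if vals.size:
                acc.setdefault((dom, "silent"), []).append(float(vals.mean()))
    rows = {}
    for (dom, cls), vals in sorted(acc.items()):
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        rows[(dom, cls)] = {"mean": float(arr.mean()), "sem": sem, "n": arr.size}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["domain", "feature_class"])
    return out
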