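"""Synthetic genome, track, sequence and expression generator.

Emulates the genomic structure the downstream analysis assumes: a small
chr4-like arm (~1.2 Mb, ~80 large multi-exon genes, ~30% repeat density)
with a repeat-rich centromere-proximal block, a pericentric-heterochromatin
-like region, and a euchromatin-like arm; gene-body vs TSS mark
architecture (HP1a/H3K9me3/POF enriched over active chr4 gene bodies,
depleted at TSSs); planted paused/non-paused genes in a GRO-seq-like
read-density track; promoter sequences with domain-specific motif planting
rates and GC content; and mutant conditions applying feature-class-specific
multiplicative retention factors to mark means and per-gene down-scaling to
expression.

Everything is deterministic under a single integer master seed; each
generator draws from its own labelled sub-stream so adding one stage never
perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (
    DomainPartition,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    ProbeTrack,
    ReadDensityTrack,
)

# feature classes used by the mark architecture, lowest to highest priority
CLASS_BACKGROUND = 0
CLASS_REPEAT = 1
CLASS_SILENT = 2
CLASS_ACTIVE_BODY = 3
CLASS_TSS = 4
CLASS_NAMES = {
    CLASS_BACKGROUND: "background",
    CLASS_REPEAT: "repeat",
    CLASS_SILENT: "silent",
    CLASS_ACTIVE_BODY: "active_body",
    CLASS_TSS: "tss",
}
TSS_FLANK = 500  # TSS feature class spans TSS +/- 500 bp


class ConfigError(ValueError):
    pass


@dataclass
class DomainConfig:
    """One simulated genomic domain (a contiguous block on one chrom)."""

    label: str
    chrom: str
    start: int
    length: int
    n_genes: int
    gene_length_median: float = 2000.0
    gene_length_sigma: float = 0.45  # lognormal sigma (natural log)
    exon_median: int = 3
    repeat_density: float = 0.1
    gc: float = 0.42
    active_fraction: float = 0.5
    paused_fraction: float = 0.1
    motif_rates: dict = field(default_factory=dict)  # motif name -> planting rate

    def validate(self):
        for frac in (self.repeat_density, self.gc, self.active_fraction,
                     self.paused_fraction, *self.motif_rates.values()):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(f"{self.label}: fraction {frac} outside [0,1]")
        if self.length <= 0 or self.n_genes < 0:
            raise ConfigError(f"{self.label}: bad length/gene count")


def _default_domains() -> list[DomainConfig]:
    return [
        DomainConfig(
            label="euchromatin", chrom="chr2L", start=0, length=2_000_000,
            n_genes=500, gene_length_median=1907, exon_median=3,
            repeat_density=0.05, gc=0.43, active_fraction=0.52,
            paused_fraction=0.15,
            motif_rates={"TRL": 0.24, "iTRL": 0.25, "PB": 0.10, "Inr": 0.40},
        ),
        DomainConfig(
            label="pericentric_heterochromatin", chrom="chr2LHet", start=0,
            length=400_000, n_genes=60, gene_length_median=1844, exon_median=2,
            repeat_density=0.35, gc=0.38, active_fraction=0.54,
            paused_fraction=0.125,
            motif_rates={"TRL": 0.20, "iTRL": 0.21, "PB": 0.10, "Inr": 0.40},
        ),
        DomainConfig(
            label="chr4_proximal", chrom="chr4", start=0, length=70_000,
            n_genes=2, gene_length_median=4000, exon_median=3,
            repeat_density=0.55, gc=0.36, active_fraction=0.5,
            paused_fraction=0.0,
            motif_rates={"TRL": 0.11, "iTRL": 0.13, "PB": 0.10, "Inr": 0.40},
        ),
        DomainConfig(
            label="chr4", chrom="chr4", start=70_000, length=1_200_000,
            n_genes=80, gene_length_median=8001, exon_median=6,
            repeat_density=0.30, gc=0.36, active_fraction=0.54,
            paused_fraction=0.016,
            motif_rates={"TRL": 0.11, "iTRL": 0.13, "PB": 0.10, "Inr": 0.40},
        ),
    ]


def _default_marks() -> dict:
    """mark -> domain label -> feature class name -> mean M.

    Unlisted (mark, domain, class) combinations sit at the background mean.
    The chr4-like arm carries HP1a/H3K9me3/POF over active gene bodies with
    TSS depletion; pericentric heterochromatin carries HP1a/H3K9me2/me3 but
    no POF; the euchromatin-like arm is unenriched for silencing marks.
    """
    het = {"tss": 0.2, "active_body": 1.5, "silent": 1.2, "repeat": 1.5}
    return {
        "HP1a": {
            "chr4": {"tss": 0.2, "active_body": 2.0, "silent": 1.0, "repeat": 1.2},
            "chr4_proximal": dict(het),
            "pericentric_heterochromatin": dict(het),
        },
        "H3K9me2": {
            "chr4": {"tss": 0.1, "active_body": 1.2, "silent": 1.0, "repeat": 1.0},
            "chr4_proximal": dict(het),
            "pericentric_heterochromatin": {"tss": 0.2, "active_body": 1.8,
                                            "silent": 1.6, "repeat": 1.8},
        },
        "H3K9me3": {
            "chr4": {"tss": 0.2, "active_body": 1.8, "silent": 0.8, "repeat": 1.0},
            "chr4_proximal": dict(het),
            "pericentric_heterochromatin": {"tss": 0.2, "active_body": 1.5,
                                            "silent": 1.3, "repeat": 1.5},
        },
        "POF": {
            "chr4": {"tss": 0.3, "active_body": 2.0, "silent": 0.3, "repeat": 0.2},
        },
        "PolII": {
            "euchromatin": {"tss": 1.5, "active_body": 0.8},
            "pericentric_heterochromatin": {"tss": 1.2, "active_body": 0.6},
            "chr4": {"tss": 1.5, "active_body": 0.8},
            "chr4_proximal": {"tss": 1.2, "active_body": 0.6},
        },
    }


def _default_mutants() -> dict:
    """mutant -> mark -> domain -> class -> multiplicative retention.

    Missing entries default to 1 (no effect). Defaults: the HP1a-null
    condition retains 11.1% of H3K9me2 and 33.3% of H3K9me3 on the chr4-like
    arm and loses nearly all HP1a peaks; the pof mutant loses HP1a over chr4
    gene bodies but keeps repeat-proximal HP1a, supporting the
    distance-to-repeat contrast.
    """
    all_classes = ("tss", "active_body", "silent", "repeat")

    def flat(domains, factor, classes=all_classes):
        return {d: {c: factor for c in classes} for d in domains}

    het_domains = ("chr4", "chr4_proximal", "pericentric_heterochromatin")
    return {
        "Su(var)205": {
            "HP1a": flat(het_domains, 0.04),
            "H3K9me2": {**flat(("chr4", "chr4_proximal"), 0.111),
                        **flat(("pericentric_heterochromatin",), 0.3)},
            "H3K9me3": {**flat(("chr4", "chr4_proximal"), 0.333),
                        **flat(("pericentric_heterochromatin",), 0.3)},
            "PolII": {"chr4": {"active_body": 0.5}},
        },
        "pof": {
            "HP1a": {"chr4": {"tss": 0.1, "active_body": 0.1, "silent": 0.1,
                              "repeat": 1.0},
                     "chr4_proximal": {"tss": 0.1, "active_body": 0.1,
                                       "silent": 0.1, "repeat": 1.0}},
            "POF": flat(("chr4", "chr4_proximal"), 0.05),
            "H3K9me3": flat(("chr4",), 0.3),
            "PolII": {"chr4": {"active_body": 0.6}},
        },
    }


@dataclass
class SimConfig:
    seed: int = 0
    domains: list[DomainConfig] = field(default_factory=_default_domains)
    marks: dict = field(default_factory=_default_marks)
    mutants: dict = field(default_factory=_default_mutants)
    noise_sd: float = 0.3         # probe-level Gaussian M noise (free parameter)
    background_mean: float = 0.0  # M of unenriched probes
    probe_spacing: int = 100
    # GRO-seq-like read density
    lambda_body: float = 0.5      # reads/bp over active gene bodies
    lambda_background: float = 0.0  # off-gene rate; 0 keeps 0/0 as the
    #                                 polymerase-association rule
    pause_multiplier: float = 150.0  # extra rate over the pause window, x lambda_body
    pause_window: int = 50           # bp; pause sits 25-75 bp downstream of TSS
    pause_offset: int = 25
    # promoter sequences
    promoter_up: int = 200
    promoter_down: int = 200
    motif_patterns: dict = field(default_factory=lambda: {
        "TRL": ("GAGAG", (-200, 200)),
        "iTRL": ("CTCTC", (-200, 200)),
        "PB": ("KCGRWCG", (-60, 60)),
        "Inr": ("TCAGTY", (-200, 200)),
    })
    # expression
    expression_unit: str = "RPKM"
    expression_context: str = "cell_line"
    mutant_down_fraction: dict = field(
        default_factory=lambda: {"chr4": 0.8})
    mutant_down_factor_range: tuple = (0.2, 0.6)
    expression_noise_sd_log2: float = 0.0
    # repeats / packing
    repeat_length_mean: float = 400.0
    min_repeat_length: int = 60
    n_overlapping_pairs: int = 0  # extra genes planted to overlap existing ones

    def validate(self):
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.pause_multiplier < 1:
            raise ConfigError("pause_multiplier < 1 is not a pause")
        for dom in self.domains:
            dom.validate()
        for mut, marks in self.mutants.items():
            for mark, doms in marks.items():
                for dom, classes in doms.items():
                    for cls, r in classes.items():
                        if r < 0:
                            raise ConfigError(
                                f"{mut}/{mark}/{dom}/{cls}: retention {r} < 0")
        for name, (pat, (a, b)) in self.motif_patterns.items():
            if b - a < len(pat):
                raise ConfigError(f"motif {name}: window shorter than motif")

    def rng(self, label: str) -> np.random.Generator:
        """Labelled, seed-derived sub-stream."""
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])

    def domain(self, label: str) -> DomainConfig:
        for d in self.domains:
            if d.label == label:
                return d
        raise ConfigError(f"no domain {label!r}")

    def chrom_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.domains:
            out[d.chrom] = max(out.get(d.chrom, 0), d.start + d.length)
        return out

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimAnnotation:
    genes: list[GeneModel]
    repeats: list[GenomicInterval]
    partition: DomainPartition
    chrom_lengths: dict[str, int]
    # ground truth, keyed by gene_id
    active: dict[str, bool]
    paused: dict[str, bool]
    domain_of: dict[str, str]

    def genes_in_domain(self, label: str) -> list[GeneModel]:
        return [g for g in self.genes if self.domain_of[g.gene_id] == label]


# ---------------------------------------------------------------------------
# annotation


def _draw_gene_structure(rng, length: int, exon_median: int, chrom, start, strand):
    """Split a gene span into alternating exon/intron segments."""
    k = 1 + rng.poisson(max(0, exon_median - 1))
    min_seg = 20
    while k > 1 and length < min_seg * (2 * k - 1):
        k -= 1
    n_seg = 2 * k - 1
    w = rng.exponential(size=n_seg)
    extra = np.floor((length - min_seg * n_seg) * w / w.sum()).astype(int)
    seg = min_seg + extra
    seg[-1] += length - seg.sum()
    exons = []
    pos = start
    for i, s in enumerate(seg):
        if i % 2 == 0:
            exons.append(GenomicInterval(chrom, pos, pos + int(s), strand))
        pos += int(s)
    return exons


def generate_annotation(cfg: SimConfig) -> SimAnnotation:
    """Pack genes and repeats into each domain; assign activity and pausing."""
    cfg.validate()
    rng = cfg.rng("annotation")
    genes: list[GeneModel] = []
    repeats: list[GenomicInterval] = []
    regions = []
    active: dict[str, bool] = {}
    domain_of: dict[str, str] = {}
    gene_counter = 0

    for dom in cfg.domains:
        regions.append(
            (GenomicInterval(dom.chrom, dom.start, dom.start + dom.length), dom.label)
        )
        n = dom.n_genes
        lengths = np.maximum(
            200,
            np.round(
                dom.gene_length_median
                * np.exp(rng.normal(0.0, dom.gene_length_sigma, size=n))
            ).astype(int),
        ) if n else np.empty(0, int)
        total_gene = int(lengths.sum())
        if total_gene > 0.92 * dom.length:
            raise ConfigError(
                f"{dom.label}: genes ({total_gene} bp) + repeats cannot fit "
                f"in {dom.length} bp"
            )
        # sequential packing with random (exponential-profile) gaps
        gap_w = rng.exponential(size=n + 1)
        gaps = np.floor((dom.length - total_gene) * gap_w / gap_w.sum()).astype(int)
        cursor = dom.start
        dom_genes = []
        for i in range(n):
            cursor += int(gaps[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gene_counter:05d}"
            gene_counter += 1
            exons = _draw_gene_structure(
                rng, int(lengths[i]), dom.exon_median, dom.chrom, cursor, strand
            )
            g = GeneModel(
                gene_id=gid,
                interval=GenomicInterval(dom.chrom, cursor, cursor + int(lengths[i]),
                                         strand),
                exons=exons,
            )
            dom_genes.append(g)
            domain_of[gid] = dom.label
            cursor += int(lengths[i])

        # repeats fill intergenic space first, then introns
        target = int(round(dom.repeat_density * dom.length))
        gaps_pool = []
        prev = dom.start
        for g in dom_genes:
            if g.interval.start > prev:
                gaps_pool.append([prev, g.interval.start])
            prev = g.interval.end
        if dom.start + dom.length > prev:
            gaps_pool.append([prev, dom.start + dom.length])
        intron_pool = []
        for g in dom_genes:
            for a, b in zip(g.exons, g.exons[1:]):
                intron_pool.append([a.end, b.start])
        placed = 0
        for pool in (gaps_pool, intron_pool):
            order = rng.permutation(len(pool))
            queue = [pool[i] for i in order]
            while queue and placed < target:
                s, e = queue.pop()
                avail = e - s
                if avail < cfg.min_repeat_length:
                    continue
                rep_len = int(
                    min(
                        avail,
                        target - placed,
                        cfg.min_repeat_length + rng.exponential(cfg.repeat_length_mean),
                    )
                )
                if rep_len < cfg.min_repeat_length:
                    rep_len = cfg.min_repeat_length
                off = int(rng.integers(0, avail - rep_len + 1))
                repeats.append(GenomicInterval(dom.chrom, s + off, s + off + rep_len))
                placed += rep_len
                if s + off - s >= cfg.min_repeat_length:
                    queue.append([s, s + off])
                if e - (s + off + rep_len) >= cfg.min_repeat_length:
                    queue.append([s + off + rep_len, e])
            if placed >= target:
                break

        # activity: a fixed fraction of genes per domain is expressed
        n_active = int(round(dom.active_fraction * n))
        act_idx = rng.choice(n, size=n_active, replace=False) if n else []
        is_active = np.zeros(n, bool)
        is_active[list(act_idx)] = True
        for g, a in zip(dom_genes, is_active):
            active[g.gene_id] = bool(a)
        genes.extend(dom_genes)

    # optional overlapping genes, to exercise the pausing eligibility filter
    if cfg.n_overlapping_pairs:
        candidates = [g for g in genes if g.length >= 1000]
        picks = rng.choice(len(candidates), size=min(cfg.n_overlapping_pairs,
                                                     len(candidates)), replace=False)
        for i in picks:
            host = candidates[int(i)]
            shift = host.length // 2
            iv = GenomicInterval(host.chrom, host.interval.start + shift,
                                 host.interval.end + shift, host.strand)
            gid = f"gene{gene_counter:05d}"
            gene_counter += 1
            g = GeneModel(gene_id=gid, interval=iv,
                          exons=[GenomicInterval(iv.chrom, iv.start, iv.end,
                                                 iv.strand)])
            genes.append(g)
            domain_of[gid] = domain_of[host.gene_id]
            active[gid] = False

    partition = DomainPartition(regions)
    repeats.sort(key=lambda r: (r.chrom, r.start))

    # pausing truth: planted among active, PI-eligible genes of each domain
    paused = {g.gene_id: False for g in genes}
    eligible_ids = {g.gene_id for g in _pi_eligible(genes)}
    prng = cfg.rng("pausing-truth")
    for dom in cfg.domains:
        pool = [
            g.gene_id
            for g in genes
            if domain_of[g.gene_id] == dom.label
            and active[g.gene_id]
            and g.gene_id in eligible_ids
        ]
        n_paused = int(round(dom.paused_fraction * len(pool)))
        for gid in prng.choice(len(pool), size=n_paused, replace=False):
            paused[pool[int(gid)]] = True

    return SimAnnotation(
        genes=genes,
        repeats=repeats,
        partition=partition,
        chrom_lengths=cfg.chrom_lengths(),
        active=active,
        paused=paused,
        domain_of=domain_of,
    )


def _pi_eligible(genes: list[GeneModel]) -> list[GeneModel]:
    # local copy of the pausing filter to avoid a circular import
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    keep = []
    for glist in by_chrom.values():
        glist = sorted(glist, key=lambda g: g.interval.start)
        bad = set()
        for a, b in zip(glist, glist[1:]):
            if a.interval.end > b.interval.start:
                bad.add(a.gene_id)
                bad.add(b.gene_id)
        keep.extend(
            g for g in glist if g.length >= 500 and g.gene_id not in bad
        )
    return keep


# ---------------------------------------------------------------------------
# feature-class maps (shared by tracks)


def feature_class_arrays(cfg: SimConfig, ann: SimAnnotation) -> dict[str, np.ndarray]:
    """Per-chrom uint8 arrays of feature class codes, painted in priority order."""
    arrays = {
        chrom: np.zeros(length, dtype=np.uint8)
        for chrom, length in ann.chrom_lengths.items()
    }
    for rep in ann.repeats:
        arrays[rep.chrom][rep.start: rep.end] = CLASS_REPEAT
    for g in ann.genes:
        if not ann.active[g.gene_id]:
            arrays[g.chrom][g.interval.start: g.interval.end] = CLASS_SILENT
    for g in ann.genes:
        if ann.active[g.gene_id]:
            arrays[g.chrom][g.interval.start: g.interval.end] = CLASS_ACTIVE_BODY
    for g in ann.genes:
        if ann.active[g.gene_id]:
            lo = max(0, g.tss - TSS_FLANK)
            hi = min(arrays[g.chrom].size, g.tss + TSS_FLANK)
            arrays[g.chrom][lo:hi] = CLASS_TSS
    return arrays


def _domain_label_arrays(ann: SimAnnotation) -> dict[str, np.ndarray]:
    labels = ann.partition.labels()
    index = {lab: i + 1 for i, lab in enumerate(labels)}
    arrays = {
        chrom: np.zeros(length, dtype=np.uint8)
        for chrom, length in ann.chrom_lengths.items()
    }
    for iv, lab in ann.partition.regions:
        arrays[iv.chrom][iv.start: iv.end] = index[lab]
    return arrays, {v: k for k, v in index.items()}


# ---------------------------------------------------------------------------
# tracks


def generate_tracks(
    cfg: SimConfig,
    ann: SimAnnotation,
    marks: list[str] | None = None,
    conditions: list[str] | None = None,
) -> dict[tuple[str, str], ProbeTrack]:
    """Probe tracks per (mark, condition); WT plus any configured mutants.

    Probe M = feature-class mean for the probe's domain (times the mutant's
    retention factor, if any) + N(0, noise_sd).
    """
    cfg.validate()
    marks = marks if marks is not None else sorted(cfg.marks)
    conditions = conditions if conditions is not None else ["WT", *sorted(cfg.mutants)]
    for cond in conditions:
        if cond != "WT" and cond not in cfg.mutants:
            raise ConfigError(f"unknown condition {cond!r}")
    for mark in marks:
        if mark not in cfg.marks:
            raise ConfigError(f"unknown mark {mark!r}")

    class_arr = feature_class_arrays(cfg, ann)
    dom_arr, dom_names = _domain_label_arrays(ann)

    # per-chrom probe grids and their (class, domain) codes
    grids = {}
    for chrom, length in sorted(ann.chrom_lengths.items()):
        pos = np.arange(cfg.probe_spacing // 2, length, cfg.probe_spacing,
                        dtype=np.int64)
        grids[chrom] = (pos, class_arr[chrom][pos], dom_arr[chrom][pos])

    out: dict[tuple[str, str], ProbeTrack] = {}
    for mark in marks:
        arch = cfg.marks[mark]
        for cond in conditions:
            rng = cfg.rng(f"track/{mark}/{cond}")
            data = {}
            for chrom, (pos, cls_codes, dom_codes) in grids.items():
                means = np.full(pos.size, cfg.background_mean)
                for dcode, dlabel in dom_names.items():
                    dom_means = arch.get(dlabel, {})
                    for ccode, cname in CLASS_NAMES.items():
                        if cname == "background":
                            continue
                        mu = dom_means.get(cname)
                        if mu is None:
                            continue
                        if cond != "WT":
                            mu = mu * (
                                cfg.mutants[cond]
                                .get(mark, {})
                                .get(dlabel, {})
                                .get(cname, 1.0)
                            )
                        means[(cls_codes == ccode) & (dom_codes == dcode)] = mu
                data[chrom] = (pos, means + rng.normal(0.0, cfg.noise_sd, pos.size))
            out[(mark, cond)] = ProbeTrack(mark=mark, condition=cond, data=data)
    return out


# ---------------------------------------------------------------------------
# read density


def generate_readdensity(cfg: SimConfig, ann: SimAnnotation) -> ReadDensityTrack:
    """Stranded Poisson per-base counts with planted promoter-proximal pausing.

    Active genes carry ``lambda_body`` reads/bp on their strand; planted
    paused genes additionally carry ``lambda_body * pause_multiplier`` over a
    ``pause_window``-bp window starting ``pause_offset`` bp downstream of the
    TSS (the promoter-proximal pause sits within the first ~75 bp).
    """
    cfg.validate()
    rng = cfg.rng("readdensity")
    counts = {}
    for chrom, length in sorted(ann.chrom_lengths.items()):
        for strand in ("+", "-"):
            rate = np.full(length, cfg.lambda_background)
            for g in ann.genes:
                if g.chrom != chrom or g.strand != strand or not ann.active[g.gene_id]:
                    continue
                rate[g.interval.start: g.interval.end] += cfg.lambda_body
                if ann.paused[g.gene_id]:
                    if g.oriented_forward:
                        lo = g.tss + cfg.pause_offset
                        hi = lo + cfg.pause_window
                    else:
                        hi = g.tss - cfg.pause_offset + 1
                        lo = hi - cfg.pause_window
                    lo, hi = max(0, lo), min(length, hi)
                    rate[lo:hi] += cfg.lambda_body * cfg.pause_multiplier
            counts[(chrom, strand)] = rng.poisson(rate)
    return ReadDensityTrack(counts=counts, chrom_lengths=dict(ann.chrom_lengths))


# ---------------------------------------------------------------------------
# promoter sequences


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _concrete_instance(rng, pattern: str) -> str:
    return "".join(IUPAC[c][int(rng.integers(0, len(IUPAC[c])))] for c in pattern)


def generate_sequences(cfg: SimConfig, ann: SimAnnotation) -> dict[str, str]:
    """TSS-oriented promoter sequences (TSS - up .. TSS + down) per gene.

    Background is i.i.d. at the domain's GC; each configured motif is
    independently planted with its domain rate at a uniform position inside
    its scan window. The TSS sits at string index ``promoter_up``.
    """
    cfg.validate()
    rng = cfg.rng("sequences")
    seq_len = cfg.promoter_up + cfg.promoter_down
    out = {}
    for g in sorted(ann.genes, key=lambda g: g.gene_id):
        dom = cfg.domain(ann.domain_of[g.gene_id])
        gc = dom.gc
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = list("ACGT"[i] for i in rng.choice(4, size=seq_len, p=p))
        for name, (pattern, (a, b)) in sorted(cfg.motif_patterns.items()):
            rate = dom.motif_rates.get(name, 0.0)
            if rng.random() >= rate:
                continue
            lo = cfg.promoter_up + a
            hi = cfg.promoter_up + b - len(pattern)
            lo = max(0, lo)
            hi = min(seq_len - len(pattern), hi)
            if hi < lo:
                raise ConfigError(f"motif {name}: window shorter than motif")
            start = int(rng.integers(lo, hi + 1))
            inst = _concrete_instance(rng, pattern)
            seq[start: start + len(pattern)] = list(inst)
        out[g.gene_id] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    cfg: SimConfig, ann: SimAnnotation, mutant: str | None = None
) -> tuple[ExpressionTable, ExpressionTable, dict[str, float]]:
    """WT and mutant expression tables plus the per-gene truth factors.

    WT values are log-normal, with planted-active genes above the declared
    expressed threshold and silent genes below it. The mutant table applies
    a per-gene down-scaling factor to ``mutant_down_fraction`` of each
    domain's genes (chr4-like by default), optionally with symmetric
    log-scale noise on every gene.
    """
    cfg.validate()
    rng = cfg.rng(f"expression/{mutant or 'default'}")
    thr = 0.6 if cfg.expression_context == "cell_line" else 0.4
    if cfg.expression_unit == "FPKM":
        # active iff log2(v+1) > 1.4
        def draw_active():
            return float(2 ** (1.4 + abs(rng.normal(0, 1.0))) - 1)

        def draw_silent():
            return float(2 ** (rng.uniform(0, 1.2)) - 1)
    else:
        def draw_active():
            return float(10 ** (thr + abs(rng.normal(0, 0.5))) - 1)

        def draw_silent():
            return float(10 ** (rng.uniform(0, 0.8 * thr)) - 1)

    wt = {}
    for g in sorted(ann.genes, key=lambda g: g.gene_id):
        wt[g.gene_id] = draw_active() if ann.active[g.gene_id] else draw_silent()

    factors = {gid: 1.0 for gid in wt}
    for label, frac in cfg.mutant_down_fraction.items():
        pool = sorted(
            gid for gid in wt if ann.domain_of[gid] == label
        )
        n_down = int(round(frac * len(pool)))
        lo, hi = cfg.mutant_down_factor_range
        for i in rng.choice(len(pool), size=n_down, replace=False):
            factors[pool[int(i)]] = float(rng.uniform(lo, hi))

    sd = cfg.expression_noise_sd_log2
    mut = {}
    for gid, v in wt.items():
        noise = float(2 ** rng.normal(0.0, sd)) if sd > 0 else 1.0
        mut[gid] = v * factors[gid] * noise

    unit = cfg.expression_unit
    return ExpressionTable(wt, unit), ExpressionTable(mut, unit), factors
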