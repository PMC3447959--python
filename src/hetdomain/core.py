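"""Core domain types shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere inside the package; format
readers and writers convert at the boundary (GFF3 is 1-based inclusive on
disk). Strand ``.`` is treated as ``+`` wherever a TSS-relative orientation
is needed, so unstranded annotation behaves deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")

DOMAIN_LABELS = (
    "euchromatin",
    "pericentric_heterochromatin",
    "chr4",
    "chr4_proximal",
)

UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene: its span, exon structure, strand and expression level.

    ``tss``/``tes`` follow the strand: for ``+`` (and ``.``) the TSS is
    ``interval.start``; for ``-`` it is ``interval.end - 1``.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    expression: float = 0.0

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id} has zero exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValidationError(f"gene {self.gene_id}: exon on wrong chrom")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon outside gene interval"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = ex.end
        if self.expression < 0:
            raise ValidationError(f"gene {self.gene_id}: negative expression")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def oriented_forward(self) -> bool:
        """Strand '.' orients like '+'."""
        return self.strand != "-"

    @property
    def tss(self) -> int:
        return self.interval.start if self.oriented_forward else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.oriented_forward else self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class DomainPartition:
    """Non-overlapping labelled intervals covering the analysed genome.

    Genes are assigned by TSS location; a TSS outside every interval gets
    the explicit label ``unassigned`` rather than being dropped.
    """

    regions: list[tuple[GenomicInterval, str]]

    def __post_init__(self):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv, _label in self.regions:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValidationError("domain intervals overlap")

    def label_at(self, chrom: str, pos: int) -> str:
        for iv, label in self.regions:
            if iv.contains(chrom, pos):
                return label
        return UNASSIGNED

    def label_of_gene(self, gene: GeneModel) -> str:
        return self.label_at(gene.chrom, gene.tss)

    def labels(self) -> list[str]:
        seen: list[str] = []
        for _iv, label in self.regions:
            if label not in seen:
                seen.append(label)
        return seen

    def regions_for(self, label: str) -> list[GenomicInterval]:
        return [iv for iv, lab in self.regions if lab == label]


def assign_domain(gene: GeneModel, partition: DomainPartition) -> str:
    """Domain label of the interval containing the gene's TSS."""
    return partition.label_of_gene(gene)


@dataclass
class ProbeTrack:
    """Ordered probe-level enrichment track for one mark and condition.

    ``data`` maps chrom -> (positions, m_values); positions are strictly
    increasing int64 arrays, values are finite float64 (M = log2 ChIP/input).
    """

    mark: str
    condition: str
    data: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, val) in self.data.items():
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=np.float64)
            if pos.shape != val.shape:
                raise ValidationError(f"{chrom}: position/value length mismatch")
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValidationError(f"{chrom}: probe positions not increasing")
            if not np.all(np.isfinite(val)):
                raise ValidationError(f"{chrom}: non-finite M-value")
            clean[chrom] = (pos, val)
        self.data = clean

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    @property
    def n_probes(self) -> int:
        return sum(pos.size for pos, _ in self.data.values())

    def values(self, chrom: str) -> np.ndarray:
        return self.data[chrom][1]

    def positions(self, chrom: str) -> np.ndarray:
        return self.data[chrom][0]

    def all_values(self) -> np.ndarray:
        if not self.data:
            return np.empty(0)
        return np.concatenate([self.data[c][1] for c in self.chroms])

    def slice_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """M-values of probes with start <= position < end."""
        pos, val = self.data[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return val[lo:hi]

    def slice_probes(self, chrom: str, start: int, end: int):
        pos, val = self.data[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi], val[lo:hi]

    def same_grid(self, other: "ProbeTrack") -> bool:
        if set(self.data) != set(other.data):
            return False
        return all(
            np.array_equal(self.data[c][0], other.data[c][0]) for c in self.data
        )

    def with_values(self, new: dict[str, np.ndarray], condition: str | None = None):
        data = {c: (self.data[c][0].copy(), np.asarray(new[c], float)) for c in self.data}
        return ProbeTrack(self.mark, condition or self.condition, data)


@dataclass
class ReadDensityTrack:
    """Stranded per-base read counts (GRO-seq-like).

    ``counts`` maps (chrom, strand) -> non-negative int array of chrom length.
    """

    counts: dict[tuple[str, str], np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self):
        for (chrom, strand), arr in list(self.counts.items()):
            arr = np.asarray(arr)
            if strand not in ("+", "-"):
                raise ValidationError(f"bad strand {strand!r}")
            if np.any(arr < 0):
                raise ValidationError(f"{chrom}{strand}: negative counts")
            if arr.size != self.chrom_lengths.get(chrom, arr.size):
                raise ValidationError(f"{chrom}{strand}: length mismatch")
            self.counts[(chrom, strand)] = arr
            self.chrom_lengths.setdefault(chrom, arr.size)

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Total reads in [start, end) on one strand; clips to chrom bounds."""
        arr = self.counts.get((chrom, strand))
        if arr is None:
            return 0.0
        start = max(0, start)
        end = min(arr.size, end)
        if end <= start:
            return 0.0
        return float(arr[start:end].sum())


@dataclass
class EnrichedRegion:
    interval: GenomicInterval
    score: float  # mean smoothed M over the region
    n_probes: int = 0


@dataclass
class EnrichedRegionSet:
    """Sorted, non-overlapping significantly enriched regions."""

    regions: list[EnrichedRegion]
    fdr_threshold: float

    def __post_init__(self):
        if not (0 < self.fdr_threshold < 1):
            raise ValidationError("fdr_threshold must be in (0,1)")
        self.regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
        for a, b in zip(self.regions, self.regions[1:]):
            if a.interval.overlaps(b.interval):
                raise ValidationError("enriched regions overlap")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def total_bp(self, within: list[GenomicInterval] | None = None) -> int:
        if within is None:
            return sum(len(r.interval) for r in self.regions)
        total = 0
        for r in self.regions:
            for iv in within:
                if r.interval.overlaps(iv):
                    total += min(r.interval.end, iv.end) - max(r.interval.start, iv.start)
        return total


@dataclass
class ExpressionTable:
    """Per-gene expression values in a declared unit (RPKM or FPKM)."""

    values: dict[str, float]
    unit: str = "RPKM"

    def __post_init__(self):
        if self.unit not in ("RPKM", "FPKM"):
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        for g, v in self.values.items():
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"gene {g}: invalid expression {v}")

    def __getitem__(self, gene_id: str) -> float:
        return self.values[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def __len__(self) -> int:
        return len(self.values)

    def gene_ids(self) -> list[str]:
        return sorted(self.values)
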