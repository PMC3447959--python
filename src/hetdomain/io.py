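"""Readers and writers for the standard text formats the pipeline touches.

GFF3 (1-based inclusive on disk) and BED12 for gene models, WIG
(fixedStep/variableStep) and bedGraph for probe tracks, bedGraph for
stranded read density, FASTA for promoter sequences, TSV for expression
tables, BED for repeats/domains/regions. All writers emit deterministic
column order and records sorted by (chrom, start, id).

Probe position conventions: interval-valued input (bedGraph, spanned WIG
steps) maps a record to a single probe at the interval midpoint (floored),
except fixedStep/variableStep WIG where the declared start coordinate is
the probe position — array platforms report point-like probes.
"""

from __future__ import annotations

import os
from collections import defaultdict

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DomainPartition,
    EnrichedRegion,
    EnrichedRegionSet,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    ProbeTrack,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12, sorted by (chrom, start, gene_id)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".gff", ".gff3"):
        genes = _read_gff3(path)
    elif ext == ".bed":
        genes = _read_bed12(path)
    else:
        raise ParseError(f"unrecognised annotation extension: {path}")
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils wraps sqlite/parsing errors opaquely
        raise ParseError(f"{path}: failed to parse GFF3: {exc}") from exc

    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, feat.strand or ".")
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        if not exons:
            raise ValidationError(f"gene {feat.id} has zero exons")
        genes.append(GeneModel(gene_id=feat.id, interval=iv, exons=exons))
    return genes


def _read_bed12(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            iv = GenomicInterval(chrom, start, end, strand)
            exons = [
                GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            ]
            genes.append(GeneModel(gene_id=name, interval=iv, exons=exons))
    return genes


def write_gene_models_gff3(genes: list[GeneModel], path: str) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\thetdomain\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{ex.chrom}\thetdomain\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{iv.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# probe tracks


def read_track(path: str, mark: str = "", condition: str = "WT") -> ProbeTrack:
    """Read a WIG or bedGraph file into a ProbeTrack."""
    probes: dict[str, list[tuple[int, float]]] = defaultdict(list)
    mode = None  # None => bedGraph lines; else ("fixed"|"variable", state)
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "browser")):
                continue
            if line.startswith("track"):
                mode = None
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                mode = ("fixed", int(kv["start"]) - 1, int(kv.get("step", 1)))
                continue
            if line.startswith("variableStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                mode = ("variable",)
                continue
            try:
                if mode is None:
                    f = line.split()
                    if len(f) < 4:
                        raise ParseError(
                            f"{path}:{lineno}: bedGraph needs 4 fields"
                        )
                    c, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
                    probes[c].append(((s + e) // 2, v))
                elif mode[0] == "fixed":
                    v = float(line)
                    _tag, nxt, step = mode
                    probes[chrom].append((nxt, v))
                    mode = ("fixed", nxt + step, step)
                else:
                    p_s, v_s = line.split()[:2]
                    probes[chrom].append((int(p_s) - 1, float(v_s)))
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc

    data = {}
    for c, pv in probes.items():
        pos = np.array([p for p, _ in pv], dtype=np.int64)
        val = np.array([v for _, v in pv], dtype=np.float64)
        if np.any(np.isnan(val)):
            raise ValidationError(f"{path}: NaN value on {c}")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValidationError(f"{path}: positions not increasing on {c}")
        data[c] = (pos, val)
    return ProbeTrack(mark=mark, condition=condition, data=data)


def write_track_bedgraph(track: ProbeTrack, path: str, span: int = 1) -> None:
    """Write probes as ``span``-bp bedGraph intervals centred on the probe.

    With the default span of 1 the interval is [pos, pos+1), whose midpoint
    floors back to pos, so write-then-read is an identity.
    """
    with open(path, "w") as fh:
        for chrom in track.chroms:
            pos, val = track.data[chrom]
            half = span // 2
            for p, v in zip(pos, val):
                fh.write(f"{chrom}\t{p - half}\t{p - half + span}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# read density


def write_readdensity_bedgraph(counts: np.ndarray, chrom: str, path: str) -> None:
    """Run-length-encode a per-base count array to bedGraph (zeros skipped)."""
    arr = np.asarray(counts)
    with open(path, "w") as fh:
        if arr.size == 0:
            return
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [arr.size]])
        for s, e in zip(starts, ends):
            v = arr[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")


def read_readdensity_bedgraph(path: str, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            try:
                _c, s, e, v = line.split()[:4]
                arr[int(s): int(e)] = int(float(v))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return arr


# ---------------------------------------------------------------------------
# intervals / regions / domains


def write_bed(intervals: list[GenomicInterval], path: str,
              names: list[str] | None = None,
              scores: list[float] | None = None) -> None:
    rows = sorted(
        range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start)
    )
    with open(path, "w") as fh:
        for i in rows:
            iv = intervals[i]
            name = names[i] if names else "."
            score = f"{scores[i]:.6g}" if scores else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 fields")
            strand = f[5] if len(f) > 5 and f[5] in "+-." else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_regions_bed(regions: EnrichedRegionSet, path: str) -> None:
    write_bed(
        [r.interval for r in regions.regions],
        path,
        names=[f"region_{i + 1}" for i in range(len(regions.regions))],
        scores=[r.score for r in regions.regions],
    )


def write_domains_bed(partition: DomainPartition, path: str) -> None:
    write_bed(
        [iv for iv, _ in partition.regions],
        path,
        names=[label for _, label in partition.regions],
    )


def read_domains_bed(path: str) -> DomainPartition:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: domain BED needs 4 fields")
            regions.append((GenomicInterval(f[0], int(f[1]), int(f[2])), f[3]))
    return DomainPartition(regions)


def regions_from_bed(path: str, fdr: float = 1e-3) -> EnrichedRegionSet:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            score = float(f[4]) if len(f) > 4 else 0.0
            out.append(EnrichedRegion(GenomicInterval(f[0], int(f[1]), int(f[2])), score))
    return EnrichedRegionSet(out, fdr)


# ---------------------------------------------------------------------------
# sequences and tables


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seqs[name]), id=name, description="") for name in sorted(seqs)
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_expression_tsv(table: ExpressionTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"gene_id\t{table.unit}\n")
        for g in table.gene_ids():
            fh.write(f"{g}\t{float(table.values[g])!r}\n")


def read_expression_tsv(path: str) -> ExpressionTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2 or header[0] != "gene_id":
            raise ParseError(f"{path}:1: expected header 'gene_id<TAB><unit>'")
        unit = header[1]
        values = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                g, v = line.split("\t")
                values[g] = float(v)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return ExpressionTable(values, unit)
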