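"""Gene-model parsing and junction-read evidence extraction.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted at the boundary.  A splice junction is keyed genomically by
``(chrom, strand, donor_end, acceptor_start)`` where ``donor_end`` is the
half-open end of the upstream exonic segment and ``acceptor_start`` the
start of the downstream one; strand only affects 5'/3' labelling downstream,
never the key itself, because BAM evidence is genomic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from urllib.parse import unquote

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "GeneModel",
    "JunctionKey",
    "PositionalCounts",
    "parse_gff3",
    "write_gff3",
    "extract_junction_counts",
    "read_counts_table",
    "write_counts_table",
]


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def junctions(self) -> list[tuple[int, int]]:
        """Implied (donor_end, acceptor_start) pairs between consecutive exons."""
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for t in self.transcripts for e in t.exons]
        ends = [e[1] for t in self.transcripts for e in t.exons]
        return (min(starts), max(ends))


@dataclass(frozen=True, order=True)
class JunctionKey:
    chrom: str
    strand: str
    donor_end: int
    acceptor_start: int

    def __post_init__(self):
        if self.donor_end >= self.acceptor_start:
            raise ValueError(
                f"junction donor_end {self.donor_end} must precede "
                f"acceptor_start {self.acceptor_start}"
            )

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end


@dataclass
class PositionalCounts:
    """Per-junction, per-experiment read counts indexed by read-start offset.

    The offset is the read's start position relative to the junction window
    (donor side); a position's count reflects reads *starting* there, not
    reads overlapping it.
    """

    junction: JunctionKey
    experiment_id: str
    counts: dict[int, float] = field(default_factory=dict)
    gc_fraction: float | None = None

    @property
    def total_reads(self) -> float:
        return sum(self.counts.values())

    @property
    def n_positions(self) -> int:
        return sum(1 for v in self.counts.values() if v > 0)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def _parse_attrs(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = unquote(v.strip())
    return out


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file with a gene/mRNA(or transcript)/exon hierarchy.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Malformed records (exon without a known parent transcript, start > end)
    are rejected with a logged warning; a gene whose transcripts disagree on
    strand raises ``ValueError``.
    """
    genes: dict[str, GeneModel] = {}
    tx_gene: dict[str, str] = {}
    tx_by_id: dict[str, Transcript] = {}
    tx_strand: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                log.warning("%s:%d: expected 9 columns, skipping", path, lineno)
                continue
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                log.warning("%s:%d: non-integer coordinates, skipping", path, lineno)
                continue
            if start1 > end1:
                log.warning("%s:%d: start > end, record rejected", path, lineno)
                continue
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID", f"gene_{lineno}")
                genes[gid] = GeneModel(gene_id=gid, chrom=chrom, strand=strand)
            elif ftype in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID", f"tx_{lineno}")
                parent = attrs.get("Parent")
                if parent is None or parent not in genes:
                    log.warning(
                        "%s:%d: transcript %s without known gene parent, rejected",
                        path, lineno, tid,
                    )
                    continue
                gene = genes[parent]
                if strand != gene.strand:
                    raise ValueError(
                        f"gene {parent}: transcript {tid} on strand {strand} "
                        f"conflicts with gene strand {gene.strand}"
                    )
                tx = Transcript(transcript_id=tid)
                gene.transcripts.append(tx)
                tx_gene[tid] = parent
                tx_by_id[tid] = tx
                tx_strand[tid] = strand
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None or parent not in tx_by_id:
                    log.warning(
                        "%s:%d: exon without known parent transcript, rejected",
                        path, lineno,
                    )
                    continue
                tx_by_id[parent].exons.append((start, end))

    out = []
    for gene in genes.values():
        gene.transcripts = [t for t in gene.transcripts if t.exons]
        for tx in gene.transcripts:
            tx.exons.sort()
        if gene.transcripts:
            out.append(gene)
    return out


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (exact coordinate round-trip)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            fh.write(
                f"{g.chrom}\t.\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for tx in g.transcripts:
                ts = min(e[0] for e in tx.exons)
                te = max(e[1] for e in tx.exons)
                fh.write(
                    f"{g.chrom}\t.\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (es, ee) in enumerate(sorted(tx.exons), 1):
                    fh.write(
                        f"{g.chrom}\t.\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                        f"ID={tx.transcript_id}.e{i};Parent={tx.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# BAM junction evidence
# ---------------------------------------------------------------------------


def extract_junction_counts(
    bam_path: str | Path,
    genes: Iterable[GeneModel],
    min_overhang: int = 8,
    mapq_unique: int = 255,
    experiment_id: str | None = None,
) -> list[PositionalCounts]:
    """Extract per-start-position junction read counts from an indexed BAM.

    Only uniquely mapped reads count (``mapq >= mapq_unique``, matching the
    convention where the aligner reserves the maximum MAPQ for unique hits);
    a read must align at least ``min_overhang`` bases on both sides of the
    junction.  Offsets are measured from the junction's donor side:
    ``offset = donor_end - start`` of the aligned block carrying the
    donor-side overhang, so larger offsets mean the read starts further
    upstream of the junction.
    """
    import pysam

    bam_path = Path(bam_path)
    if experiment_id is None:
        experiment_id = bam_path.stem
    try:
        bam = pysam.AlignmentFile(str(bam_path), "rb")
        if not bam.has_index():
            raise ValueError(f"BAM {bam_path} is not indexed; run samtools index")
    except OSError as e:  # pragma: no cover - pysam raises on missing index too
        raise ValueError(f"BAM {bam_path} unusable ({e}); is it indexed?") from e

    gene_list = list(genes)
    # Merge overlapping gene spans per chromosome so each region is fetched
    # once; a junction falling inside genes on opposite strands is counted
    # for neither.
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chrom, []).append(g)

    acc: dict[JunctionKey, dict[int, int]] = {}
    for chrom, cgenes in sorted(by_chrom.items()):
        if chrom not in bam.references:
            continue
        spans = sorted(g.span for g in cgenes)
        regions: list[list[int]] = []
        for s, e in spans:
            if regions and s <= regions[-1][1]:
                regions[-1][1] = max(regions[-1][1], e)
            else:
                regions.append([s, e])
        for gs, ge in regions:
            for read in bam.fetch(chrom, gs, ge):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < mapq_unique:
                    continue
                for donor_end, acceptor_start, left, right, block_start in _split_blocks(read):
                    if left < min_overhang or right < min_overhang:
                        continue
                    owners = [
                        g for g in cgenes
                        if g.span[0] <= donor_end and acceptor_start <= g.span[1]
                    ]
                    if not owners:
                        continue
                    strands = {g.strand for g in owners}
                    if len(strands) > 1:
                        log.warning(
                            "junction %s:%d-%d lies in genes on both strands; skipped",
                            chrom, donor_end, acceptor_start,
                        )
                        continue
                    key = JunctionKey(chrom, strands.pop(), donor_end, acceptor_start)
                    offset = donor_end - block_start
                    bucket = acc.setdefault(key, {})
                    bucket[offset] = bucket.get(offset, 0) + 1
    bam.close()
    return [
        PositionalCounts(junction=k, experiment_id=experiment_id, counts=dict(sorted(v.items())))
        for k, v in sorted(acc.items())
    ]


def _split_blocks(read):
    """Yield (donor_end, acceptor_start, left_overhang, right_overhang, left_block_start)
    for each N gap in the read's CIGAR."""
    pos = read.reference_start
    blocks: list[tuple[int, int]] = []  # aligned reference blocks
    gaps: list[int] = []  # index into blocks after which an N occurs
    cur_start = pos
    cur = pos
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference within a block
            cur += length
        elif op == 3:  # N
            blocks.append((cur_start, cur))
            gaps.append(len(blocks) - 1)
            cur += length
            cur_start = cur
        # I, S, H, P consume no reference
    blocks.append((cur_start, cur))
    for gi in gaps:
        donor_end = blocks[gi][1]
        acceptor_start = blocks[gi + 1][0]
        left = blocks[gi][1] - blocks[gi][0]
        right = blocks[gi + 1][1] - blocks[gi + 1][0]
        yield donor_end, acceptor_start, left, right, blocks[gi][0]


# ---------------------------------------------------------------------------
# Counts table (TSV alternative to BAM)
# ---------------------------------------------------------------------------

_TABLE_COLS = ["experiment", "chrom", "strand", "donor_end", "acceptor_start", "offset", "count"]


def read_counts_table(path: str | Path) -> list[PositionalCounts]:
    """Read per-junction positional counts from TSV.

    Columns: experiment, chrom, strand, donor_end, acceptor_start, offset,
    count, and optionally gc.  Duplicate (experiment, junction, offset) rows
    or negative counts are hard errors reporting the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "experiment": str})
    missing = [c for c in _TABLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return []
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative count at line {neg[0] + 2}")
    keycols = ["experiment", "chrom", "strand", "donor_end", "acceptor_start", "offset"]
    dup = df.duplicated(subset=keycols)
    if dup.any():
        raise ValueError(f"{path}: duplicate junction/offset row at line {dup.idxmax() + 2}")
    out = []
    group_cols = ["experiment", "chrom", "strand", "donor_end", "acceptor_start"]
    for (exp, chrom, strand, d, a), grp in df.groupby(group_cols, sort=True):
        gc = None
        if "gc" in grp.columns:
            vals = grp["gc"].dropna().unique()
            if len(vals):
                gc = float(vals[0])
        out.append(
            PositionalCounts(
                junction=JunctionKey(str(chrom), str(strand), int(d), int(a)),
                experiment_id=str(exp),
                counts={int(o): float(c) for o, c in zip(grp["offset"], grp["count"]) if c > 0},
                gc_fraction=gc,
            )
        )
    return out


def write_counts_table(counts: Iterable[PositionalCounts], path: str | Path) -> None:
    rows = []
    for pc in counts:
        for off, c in sorted(pc.counts.items()):
            row = {
                "experiment": pc.experiment_id,
                "chrom": pc.junction.chrom,
                "strand": pc.junction.strand,
                "donor_end": pc.junction.donor_end,
                "acceptor_start": pc.junction.acceptor_start,
                "offset": off,
                "count": c,
            }
            if pc.gc_fraction is not None:
                row["gc"] = pc.gc_fraction
            rows.append(row)
    cols = _TABLE_COLS + (["gc"] if any("gc" in r for r in rows) else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
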