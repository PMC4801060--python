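"""Per-gene splice graphs combining annotation with de novo junction evidence.

The graph holds merged exonic segments (annotated, de novo, or de novo
extensions of annotated exons), junction edges with provenance and
per-experiment read-evidence summaries, and optional intron-retention edges
detected from windowed intronic coverage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .annotation_io import GeneModel, JunctionKey, PositionalCounts

log = logging.getLogger(__name__)

__all__ = [
    "Exon",
    "JunctionRecord",
    "IntronEdge",
    "SpliceGraph",
    "ReliabilityFilter",
    "build_splice_graph",
    "detect_retained_introns",
    "graph_to_json",
]

ANNOTATED = "annotated"
DENOVO = "denovo"
DENOVO_EXT = "denovo_extension"


@dataclass
class Exon:
    start: int
    end: int
    origin: str = ANNOTATED
    open_ended: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def contains_boundary(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class JunctionRecord:
    key: JunctionKey
    origin: str = ANNOTATED
    # experiment_id -> (total reads, nonzero positions)
    evidence: dict[str, tuple[float, int]] = field(default_factory=dict)

    def passes(self, min_reads: float, min_positions: int, mode: str = "any") -> bool:
        if not self.evidence:
            return False
        checks = [
            total >= min_reads and npos >= min_positions
            for total, npos in self.evidence.values()
        ]
        return any(checks) if mode == "any" else all(checks)


@dataclass
class IntronEdge:
    start: int  # intron interval, 0-based half-open
    end: int
    # experiment_id -> minimum windowed average coverage across the intron
    min_window_cov: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ReliabilityFilter:
    """Evidence filter for de novo junctions: a junction is reliable if it
    appears in the annotation or has at least ``min_reads`` reads from
    ``min_positions`` distinct start positions."""

    min_reads: int = 2
    min_positions: int = 2

    def __post_init__(self):
        if self.min_reads < 1 or self.min_positions < 1:
            raise ValueError("reliability filter thresholds must be >= 1")


@dataclass
class SpliceGraph:
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)
    junctions: list[JunctionRecord] = field(default_factory=list)
    intron_edges: list[IntronEdge] = field(default_factory=list)

    def junction(self, key: JunctionKey) -> JunctionRecord | None:
        for j in self.junctions:
            if j.key == key:
                return j
        return None

    def exon_at(self, pos: int) -> Exon | None:
        """Exon whose closed boundary interval [start, end] contains pos."""
        for e in self.exons:
            if e.contains_boundary(pos):
                return e
        return None


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_splice_graph(
    gene: GeneModel,
    evidence: Sequence[PositionalCounts] = (),
    filter: ReliabilityFilter | None = None,
    max_denovo_exon: int = 500,
    flank: int = 0,
    evidence_mode: str = "any",
) -> SpliceGraph:
    """Combine annotated transcripts with reliable de novo junction evidence.

    Annotated junctions are kept even with zero reads.  A de novo junction
    must pass the reliability filter in at least one experiment (or all, with
    ``evidence_mode='all'``).  De novo splice sites falling outside annotated
    exons extend the neighbouring exon (acceptor extends the downstream
    exon's start, donor the upstream exon's end); an acceptor/donor pair
    inside one intron delimits a putative de novo exon.  Exonic regions that
    would exceed ``max_denovo_exon`` become open-ended flagged regions.
    """
    filt = filter or ReliabilityFilter()
    exons = [Exon(s, e, ANNOTATED) for s, e in
             _merge_intervals(ex for tx in gene.transcripts for ex in tx.exons)]
    graph = SpliceGraph(gene.gene_id, gene.chrom, gene.strand, exons=exons)

    ann_keys: dict[JunctionKey, JunctionRecord] = {}
    for tx in gene.transcripts:
        for d, a in tx.junctions():
            key = JunctionKey(gene.chrom, gene.strand, d, a)
            if key not in ann_keys:
                ann_keys[key] = JunctionRecord(key=key, origin=ANNOTATED)
    gs, ge = gene.span
    lo, hi = gs - flank, ge + flank

    # attach evidence; collect candidate de novo junctions
    denovo: dict[JunctionKey, JunctionRecord] = {}
    for pc in evidence:
        k = pc.junction
        if k.chrom != gene.chrom or not (lo <= k.donor_end and k.acceptor_start <= hi):
            continue
        rec = ann_keys.get(k)
        if rec is None:
            rec = denovo.setdefault(k, JunctionRecord(key=k, origin=DENOVO))
        prev = rec.evidence.get(pc.experiment_id, (0.0, 0))
        rec.evidence[pc.experiment_id] = (
            prev[0] + pc.total_reads,
            prev[1] + pc.n_positions,
        )

    reliable = {
        k: rec for k, rec in denovo.items()
        if rec.passes(filt.min_reads, filt.min_positions, evidence_mode)
    }

    # classify de novo splice sites relative to annotated exon boundaries
    def in_exon(pos: int) -> bool:
        return graph.exon_at(pos) is not None

    orphan_donors = sorted({k.donor_end for k in reliable if not in_exon(k.donor_end)})
    orphan_acceptors = sorted(
        {k.acceptor_start for k in reliable if not in_exon(k.acceptor_start)}
    )

    # acceptor followed by donor within the same intron => putative de novo exon
    used_d: set[int] = set()
    used_a: set[int] = set()
    new_exons: list[Exon] = []
    for a in orphan_acceptors:
        partners = [d for d in orphan_donors if d > a and d not in used_d
                    and not any(a < e.start < d or a < e.end < d for e in graph.exons)]
        if partners:
            d = min(partners)
            if d - a <= max_denovo_exon:
                new_exons.append(Exon(a, d, DENOVO))
            else:
                new_exons.append(Exon(a, min(d, a + max_denovo_exon), DENOVO, open_ended=True))
                log.info("%s: de novo exonic region %d-%d exceeds %d bp; open-ended",
                         gene.gene_id, a, d, max_denovo_exon)
            used_a.add(a)
            used_d.add(d)

    # lone orphan acceptors extend the downstream exon start; lone donors the
    # upstream exon end (capped; beyond the cap the region is open-ended)
    for a in orphan_acceptors:
        if a in used_a or graph.exon_at(a) is not None:
            continue
        downstream = [e for e in graph.exons if e.start >= a]
        if not downstream:
            log.warning("%s: de novo acceptor %d beyond last exon; skipped", gene.gene_id, a)
            continue
        nxt = min(downstream, key=lambda e: e.start)
        if nxt.start - a <= max_denovo_exon:
            nxt.start = a
            if nxt.origin == ANNOTATED:
                nxt.origin = DENOVO_EXT
        else:
            new_exons.append(Exon(a, a + max_denovo_exon, DENOVO, open_ended=True))
    for d in orphan_donors:
        if d in used_d or graph.exon_at(d) is not None:
            continue
        upstream = [e for e in graph.exons if e.end <= d]
        if not upstream:
            log.warning("%s: de novo donor %d before first exon; skipped", gene.gene_id, d)
            continue
        prv = max(upstream, key=lambda e: e.end)
        if d - prv.end <= max_denovo_exon:
            prv.end = d
            if prv.origin == ANNOTATED:
                prv.origin = DENOVO_EXT
        else:
            new_exons.append(Exon(d - max_denovo_exon, d, DENOVO, open_ended=True))

    graph.exons.extend(new_exons)
    graph.exons.sort(key=lambda e: (e.start, e.end))

    kept: list[JunctionRecord] = list(ann_keys.values())
    for k, rec in sorted(reliable.items()):
        d_ex = graph.exon_at(k.donor_end)
        a_ex = graph.exon_at(k.acceptor_start)
        if d_ex is None or a_ex is None:
            log.warning(
                "%s: de novo junction %d-%d shares no coordinate with any exon; skipped",
                gene.gene_id, k.donor_end, k.acceptor_start,
            )
            continue
        kept.append(rec)
    kept.sort(key=lambda r: (r.key.donor_end, r.key.acceptor_start))
    graph.junctions = kept
    return graph


CoverageFn = Callable[[str, str, int, int], np.ndarray]
"""(experiment_id, chrom, start, end) -> per-base depth array of length end-start."""


def detect_retained_introns(
    graph: SpliceGraph,
    coverage: CoverageFn,
    experiment_ids: Sequence[str],
    min_intronic_cov: float = 1.5,
    window: int = 50,
) -> SpliceGraph:
    """Add intron-retention edges where windowed intronic coverage is sustained.

    The intron between two adjacent graph exons gains a retention edge iff
    *every* fixed-width window tiled across it (last window truncated; an
    intron shorter than one window is a single window) has average coverage
    >= ``min_intronic_cov`` in at least one experiment.  The builder default
    threshold is 1.5; a relaxed evaluation mode (e.g. 0.5) is just a lower
    ``min_intronic_cov``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    graph.intron_edges = []
    closed = [e for e in graph.exons if not e.open_ended]
    for left, right in zip(closed, closed[1:]):
        istart, iend = left.end, right.start
        if iend <= istart:
            continue
        covs: dict[str, float] = {}
        for exp in experiment_ids:
            depth = np.asarray(coverage(exp, graph.chrom, istart, iend), dtype=float)
            if depth.shape[0] != iend - istart:
                raise ValueError("coverage accessor returned wrong-length array")
            mins = min(
                float(depth[s:s + window].mean())
                for s in range(0, iend - istart, window)
            )
            covs[exp] = mins
        if any(v >= min_intronic_cov for v in covs.values()):
            graph.intron_edges.append(IntronEdge(istart, iend, covs))
    return graph


def graph_to_json(graph: SpliceGraph) -> dict:
    """JSON-serializable summary consumed by the report module."""
    return {
        "gene_id": graph.gene_id,
        "chrom": graph.chrom,
        "strand": graph.strand,
        "exons": [
            {"start": e.start, "end": e.end, "origin": e.origin, "open_ended": e.open_ended}
            for e in graph.exons
        ],
        "junctions": [
            {
                "donor_end": j.key.donor_end,
                "acceptor_start": j.key.acceptor_start,
                "origin": j.origin,
                "evidence": {k: list(v) for k, v in sorted(j.evidence.items())},
            }
            for j in graph.junctions
        ],
        "intron_edges": [
            {"start": ie.start, "end": ie.end,
             "min_window_cov": dict(sorted(ie.min_window_cov.items()))}
            for ie in graph.intron_edges
        ],
    }


def save_graphs_json(graphs: Iterable[SpliceGraph], path) -> None:
    with open(path, "w") as fh:
        json.dump([graph_to_json(g) for g in graphs], fh, indent=1, sort_keys=True)
        fh.write("\n")
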