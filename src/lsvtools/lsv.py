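"""Local splicing variation (LSV) enumeration, classification and filtering.

An LSV is a split in the splice graph into or from a single reference exon:
a single-source (SS) LSV has >=2 edges leaving the reference exon in
transcript orientation, a single-target (ST) LSV >=2 edges entering it.
Intron-retention edges participate as junctions; edges touching open-ended
regions are excluded because their far boundary carries no splice-site ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation_io import JunctionKey, PositionalCounts
from .splicegraph import ANNOTATED, Exon, IntronEdge, JunctionRecord, ReliabilityFilter, SpliceGraph

__all__ = [
    "LSV",
    "enumerate_lsvs",
    "classify_lsv",
    "remove_redundant",
    "filter_existing",
    "filter_quantifiable",
]

SOURCE = "source"
TARGET = "target"


@dataclass
class LSV:
    gene_id: str
    chrom: str
    strand: str
    direction: str  # source | target
    reference_exon: tuple[int, int]
    junctions: list[JunctionRecord] = field(default_factory=list)
    intron_edge: IntronEdge | None = None
    reference_denovo: bool = False

    @property
    def lsv_id(self) -> str:
        tag = "s" if self.direction == SOURCE else "t"
        return f"{self.gene_id}:{self.reference_exon[0]}-{self.reference_exon[1]}:{tag}"

    @property
    def n_junctions(self) -> int:
        return len(self.junctions) + (1 if self.intron_edge is not None else 0)

    @property
    def is_complex(self) -> bool:
        return self.n_junctions > 2

    @property
    def is_intronic(self) -> bool:
        return self.intron_edge is not None

    @property
    def has_denovo(self) -> bool:
        return self.reference_denovo or any(j.origin != ANNOTATED for j in self.junctions)

    def edge_set(self) -> frozenset:
        edges = {(j.key.donor_end, j.key.acceptor_start) for j in self.junctions}
        if self.intron_edge is not None:
            edges.add(("ir", self.intron_edge.start, self.intron_edge.end))
        return frozenset(edges)

    def exon_footprint(self, graph: SpliceGraph) -> list[tuple[int, int]]:
        """All exon intervals touched by this LSV (reference + partners)."""
        ivals = {self.reference_exon}
        for j in self.junctions:
            for pos in (j.key.donor_end, j.key.acceptor_start):
                e = graph.exon_at(pos)
                if e is not None:
                    ivals.add(e.interval)
        return sorted(ivals)


def _edges_by_exon(graph: SpliceGraph):
    """Map each closed exon to junction edges attached on its donor (genomic
    left-exon) and acceptor (genomic right-exon) side."""
    closed = [e for e in graph.exons if not e.open_ended]
    donor_side: dict[tuple[int, int], list[JunctionRecord]] = {e.interval: [] for e in closed}
    accept_side: dict[tuple[int, int], list[JunctionRecord]] = {e.interval: [] for e in closed}

    def owner(pos):
        for e in closed:
            if e.contains_boundary(pos):
                return e
        return None

    for j in graph.junctions:
        d_ex, a_ex = owner(j.key.donor_end), owner(j.key.acceptor_start)
        if d_ex is None or a_ex is None:
            continue  # touches an open-ended region only
        donor_side[d_ex.interval].append(j)
        accept_side[a_ex.interval].append(j)
    return closed, donor_side, accept_side


def enumerate_lsvs(graph: SpliceGraph) -> list[LSV]:
    """One SS-LSV per exon with >=2 outgoing edges and one ST-LSV per exon
    with >=2 incoming edges, in transcript orientation; retention edges count
    as junctions on both flanking exons."""
    closed, donor_side, accept_side = _edges_by_exon(graph)
    ir_right: dict[tuple[int, int], IntronEdge] = {}
    ir_left: dict[tuple[int, int], IntronEdge] = {}
    for ie in graph.intron_edges:
        for e in closed:
            if e.end == ie.start:
                ir_right[e.interval] = ie  # intron extends genomically right of e
            if e.start == ie.end:
                ir_left[e.interval] = ie

    minus = graph.strand == "-"
    out: list[LSV] = []
    for e in closed:
        # genomic-right edges: junctions leaving e rightwards + intron to the right
        right_j = donor_side[e.interval]
        left_j = accept_side[e.interval]
        for genomic_side, juncs, ir in (("right", right_j, ir_right.get(e.interval)),
                                        ("left", left_j, ir_left.get(e.interval))):
            if minus:
                direction = TARGET if genomic_side == "right" else SOURCE
            else:
                direction = SOURCE if genomic_side == "right" else TARGET
            n = len(juncs) + (1 if ir is not None else 0)
            if n < 2:
                continue
            out.append(
                LSV(
                    gene_id=graph.gene_id,
                    chrom=graph.chrom,
                    strand=graph.strand,
                    direction=direction,
                    reference_exon=e.interval,
                    junctions=_order_junctions(juncs, e, minus, genomic_side),
                    intron_edge=ir,
                    reference_denovo=e.origin != ANNOTATED,
                )
            )
    out.sort(key=lambda l: l.lsv_id)
    return out


def _order_junctions(juncs: Sequence[JunctionRecord], ref: Exon, minus: bool,
                     genomic_side: str) -> list[JunctionRecord]:
    """Deterministic ordering: by reference-exon splice-site coordinate then
    partner coordinate, in transcript (strand-aware) orientation."""
    def sort_key(j: JunctionRecord):
        if genomic_side == "right":
            ref_ss, partner = j.key.donor_end, j.key.acceptor_start
        else:
            ref_ss, partner = j.key.acceptor_start, j.key.donor_end
        return (-ref_ss, -partner) if minus else (ref_ss, partner)
    return sorted(juncs, key=sort_key)


def classify_lsv(lsv: LSV, graph: SpliceGraph) -> str:
    """Canonical strand-normalized type string.

    Format: ``{s|t}|{ref_ss}e{exon_idx}.{partner_ss}`` per junction joined by
    ``|``, plus ``|i`` when a retention edge participates.  Splice-site and
    exon indices are ordinal positions in transcript orientation, so two
    LSVs with identical local graphs yield identical strings regardless of
    strand or absolute coordinates.
    """
    minus = lsv.strand == "-"
    tag = "s" if lsv.direction == SOURCE else "t"
    genomic_side = ("right" if (lsv.direction == SOURCE) != minus else "left")

    def ref_partner(j: JunctionKey) -> tuple[int, int]:
        if genomic_side == "right":
            return j.donor_end, j.acceptor_start
        return j.acceptor_start, j.donor_end

    ref_sites = sorted({ref_partner(j.key)[0] for j in lsv.junctions}, reverse=minus)
    # partner exons ordered by transcript-orientation distance from reference
    partner_exons: list[tuple[int, int]] = []
    partner_sites: dict[tuple[int, int], list[int]] = {}
    for j in lsv.junctions:
        _, p = ref_partner(j.key)
        e = graph.exon_at(p)
        ival = e.interval if e is not None else (p, p)
        if ival not in partner_sites:
            partner_sites[ival] = []
        if p not in partner_sites[ival]:
            partner_sites[ival].append(p)
    partner_exons = sorted(partner_sites, key=lambda iv: (-iv[0], -iv[1]) if minus else iv)
    for iv in partner_sites:
        partner_sites[iv].sort(reverse=minus)

    parts = [tag]
    for j in lsv.junctions:
        r, p = ref_partner(j.key)
        e = graph.exon_at(p)
        ival = e.interval if e is not None else (p, p)
        parts.append(
            f"{ref_sites.index(r) + 1}e{partner_exons.index(ival) + 1}."
            f"{partner_sites[ival].index(p) + 1}"
        )
    if lsv.intron_edge is not None:
        parts.append("i")
    return "|".join(parts)


def lsv_stats(lsv: LSV, graph: SpliceGraph) -> dict:
    """Derived structural statistics (junction/exon/splice-site counts)."""
    exons = set(lsv.exon_footprint(graph))
    donors = {j.key.donor_end for j in lsv.junctions}
    acceptors = {j.key.acceptor_start for j in lsv.junctions}
    return {
        "n_junctions": lsv.n_junctions,
        "n_exons": len(exons),
        "n_5ss": len(donors) if lsv.strand == "+" else len(acceptors),
        "n_3ss": len(acceptors) if lsv.strand == "+" else len(donors),
        "complex": lsv.is_complex,
        "intronic": lsv.is_intronic,
        "has_denovo": lsv.has_denovo,
    }


def remove_redundant(lsvs: Sequence[LSV]) -> list[LSV]:
    """Drop LSVs whose edge set is a strict subset of another retained LSV's
    edge set; for equal edge sets retain the single-source one (deterministic
    tie-break).  Cassette SS/ST pairs have different edge sets and are kept.
    """
    # visit larger edge sets first so subsets meet their superset; SS before
    # ST breaks equal-set ties in favour of the single-source LSV
    order = sorted(lsvs, key=lambda l: (-len(l.edge_set()), l.direction != SOURCE, l.lsv_id))
    kept: list[LSV] = []
    for cand in order:
        es = cand.edge_set()
        if any(es <= k.edge_set() for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda l: l.lsv_id)
    return kept


def filter_existing(
    lsvs: Sequence[LSV],
    filter: ReliabilityFilter | None = None,
    evidence_mode: str = "any",
) -> list[LSV]:
    """Keep LSVs that 'exist in the data': every junction is reliable
    (annotated, or passing the filter) and at least one junction passes the
    filter with read evidence."""
    filt = filter or ReliabilityFilter()
    out = []
    for lsv in lsvs:
        all_reliable = all(
            j.origin == ANNOTATED or j.passes(filt.min_reads, filt.min_positions, evidence_mode)
            for j in lsv.junctions
        )
        any_supported = any(
            j.passes(filt.min_reads, filt.min_positions, evidence_mode)
            for j in lsv.junctions
        ) or lsv.intron_edge is not None
        if all_reliable and any_supported:
            out.append(lsv)
    return out


def filter_quantifiable(
    lsvs: Sequence[LSV],
    counts: Mapping[JunctionKey, PositionalCounts],
    min_reads: int = 10,
    min_positions: int = 3,
) -> list[LSV]:
    """Keep LSVs with >=1 junction having >= min_reads reads across
    >= min_positions positions in the experiment being quantified.

    ``counts`` should be post-stack-removal so stacks cannot make an LSV
    quantifiable.
    """
    out = []
    for lsv in lsvs:
        for j in lsv.junctions:
            pc = counts.get(j.key)
            if pc is not None and pc.total_reads >= min_reads and pc.n_positions >= min_positions:
                out.append(lsv)
                break
    return out
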