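"""Tabular and static-HTML reporting of splice graphs and LSV posteriors.

Reports are deliberately static (no server, no interactivity): per-gene
splice-graph drawings with annotated junctions in red and de novo elements
in green, violin glyphs rendered directly from the discretized posterior
mass vectors, and pre-grouped tables (complex/binary, source/target,
intronic/exonic) standing in for interactive filters.
"""

from __future__ import annotations

import html
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lsv import LSV, classify_lsv, lsv_stats
from .quantify import DeltaPsiPosterior, PsiPosterior
from .splicegraph import ANNOTATED, SpliceGraph

__all__ = [
    "lsv_catalog",
    "write_lsv_catalog",
    "write_lsv_gff3",
    "write_psi_table",
    "write_dpsi_table",
    "render_report",
    "rtpcr_psi",
]


def lsv_catalog(lsvs: Sequence[LSV], graphs: Mapping[str, SpliceGraph]) -> pd.DataFrame:
    rows = []
    for lsv in lsvs:
        g = graphs[lsv.gene_id]
        st = lsv_stats(lsv, g)
        rows.append(
            {
                "lsv_id": lsv.lsv_id,
                "gene_id": lsv.gene_id,
                "chrom": lsv.chrom,
                "strand": lsv.strand,
                "direction": lsv.direction,
                "type_string": classify_lsv(lsv, g),
                "n_junctions": st["n_junctions"],
                "n_exons": st["n_exons"],
                "complex": st["complex"],
                "intronic": st["intronic"],
                "has_denovo": st["has_denovo"],
                "junctions": ";".join(
                    f"{j.key.donor_end}-{j.key.acceptor_start}" for j in lsv.junctions
                ),
            }
        )
    return pd.DataFrame(rows)


def write_lsv_catalog(lsvs, graphs, path: str | Path) -> None:
    lsv_catalog(lsvs, graphs).to_csv(path, sep="\t", index=False)


def write_lsv_gff3(lsvs: Sequence[LSV], graphs: Mapping[str, SpliceGraph],
                   path: str | Path) -> None:
    """Export each LSV's genomic region as a GFF3 feature (for downstream
    tools that consume event definitions)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for lsv in lsvs:
            coords = [lsv.reference_exon[0], lsv.reference_exon[1]]
            for j in lsv.junctions:
                coords += [j.key.donor_end, j.key.acceptor_start]
            s, e = min(coords), max(coords)
            fh.write(
                f"{lsv.chrom}\t.\tlsv\t{s + 1}\t{e}\t.\t{lsv.strand}\t.\t"
                f"ID={lsv.lsv_id};gene={lsv.gene_id}\n"
            )


def _mass_str(v: np.ndarray) -> str:
    return ";".join(f"{x:.6g}" for x in v)


def write_psi_table(posteriors: Sequence[PsiPosterior], path: str | Path) -> None:
    rows = []
    for p in posteriors:
        for j, key in enumerate(p.junctions):
            rows.append(
                {
                    "lsv_id": p.lsv_id,
                    "junction": f"{key.donor_end}-{key.acceptor_start}" if key else f"j{j}",
                    "expected_psi": p.expected_psi[j],
                    "low_confidence": p.low_confidence,
                    "masses": _mass_str(p.masses[j]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dpsi_table(
    posteriors: Sequence[DeltaPsiPosterior],
    path: str | Path,
    thresholds: Sequence[float] = (0.2,),
) -> None:
    rows = []
    for p in posteriors:
        probs = {c: p.prob_changing(c) for c in thresholds}
        for j, key in enumerate(p.junctions):
            row = {
                "lsv_id": p.lsv_id,
                "junction": f"{key.donor_end}-{key.acceptor_start}" if key else f"j{j}",
                "expected_dpsi": p.expected_dpsi[j],
            }
            for c in thresholds:
                row[f"p_changing_{c:g}"] = probs[c][j]
            row["masses"] = _mass_str(p.masses[j])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# SVG drawing helpers
# ---------------------------------------------------------------------------


def _violin_svg(masses: np.ndarray, domain: tuple[float, float], width=120, height=60) -> str:
    """Violin glyph drawn directly from a discretized mass vector."""
    m = np.asarray(masses, dtype=float)
    if m.sum() <= 0:
        m = np.ones_like(m)
    h = m / m.max() * (height / 2 - 2)
    n = len(m)
    xs = np.linspace(5, width - 5, n)
    mid = height / 2
    top = " ".join(f"{x:.1f},{mid - y:.1f}" for x, y in zip(xs, h))
    bot = " ".join(f"{x:.1f},{mid + y:.1f}" for x, y in zip(xs[::-1], h[::-1]))
    mean_x = 5 + (np.dot(m / m.sum(), np.linspace(domain[0], domain[1], n)) - domain[0]) / (
        domain[1] - domain[0]
    ) * (width - 10)
    return (
        f'<svg width="{width}" height="{height}">'
        f'<polygon points="{top} {bot}" fill="#7a9ec9" stroke="#335" stroke-width="0.5"/>'
        f'<line x1="{mean_x:.1f}" y1="4" x2="{mean_x:.1f}" y2="{height - 4}" '
        f'stroke="#c33" stroke-width="1.5"/></svg>'
    )


def _graph_svg(graph: SpliceGraph, width=700, height=90) -> str:
    xs = [e.start for e in graph.exons] + [e.end for e in graph.exons]
    lo, hi = min(xs), max(xs)
    span = max(hi - lo, 1)

    def sx(pos):
        return 10 + (pos - lo) / span * (width - 20)

    base = height - 25
    parts = [f'<svg width="{width}" height="{height}">']
    parts.append(
        f'<line x1="10" y1="{base}" x2="{width - 10}" y2="{base}" stroke="#999"/>'
    )
    for e in graph.exons:
        color = "#b22" if e.origin == ANNOTATED else "#2a2"
        dash = ' stroke-dasharray="3,2"' if e.open_ended else ""
        parts.append(
            f'<rect x="{sx(e.start):.1f}" y="{base - 10}" '
            f'width="{max(sx(e.end) - sx(e.start), 2):.1f}" height="20" '
            f'fill="{color}" stroke="#333"{dash}/>'
        )
    for j in graph.junctions:
        x1, x2 = sx(j.key.donor_end), sx(j.key.acceptor_start)
        color = "#b22" if j.origin == ANNOTATED else "#2a2"
        xm = (x1 + x2) / 2
        parts.append(
            f'<path d="M {x1:.1f} {base - 10} Q {xm:.1f} {base - 55} {x2:.1f} {base - 10}" '
            f'fill="none" stroke="{color}" stroke-width="1.2"/>'
        )
    for ie in graph.intron_edges:
        parts.append(
            f'<rect x="{sx(ie.start):.1f}" y="{base - 5}" '
            f'width="{max(sx(ie.end) - sx(ie.start), 2):.1f}" height="10" '
            f'fill="#fa0" opacity="0.6"/>'
        )
    parts.append("</svg>")
    return "".join(parts)


def render_report(
    graphs: Mapping[str, SpliceGraph],
    lsvs: Sequence[LSV],
    path: str | Path,
    psi: Mapping[str, PsiPosterior] | None = None,
    dpsi: Mapping[str, DeltaPsiPosterior] | None = None,
) -> None:
    """Write a static per-gene HTML report.

    Raises ``KeyError`` naming any posterior lsv_id absent from the catalog.
    """
    psi = psi or {}
    dpsi = dpsi or {}
    known = {l.lsv_id for l in lsvs}
    for lsv_id in list(psi) + list(dpsi):
        if lsv_id not in known:
            raise KeyError(f"posterior references unknown lsv_id {lsv_id}")

    by_gene: dict[str, list[LSV]] = {}
    for lsv in lsvs:
        by_gene.setdefault(lsv.gene_id, []).append(lsv)

    groups = {
        "complex": [l.lsv_id for l in lsvs if l.is_complex],
        "binary": [l.lsv_id for l in lsvs if not l.is_complex],
        "source": [l.lsv_id for l in lsvs if l.direction == "source"],
        "target": [l.lsv_id for l in lsvs if l.direction == "target"],
        "intronic": [l.lsv_id for l in lsvs if l.is_intronic],
        "exonic": [l.lsv_id for l in lsvs if not l.is_intronic],
    }

    out = ["<!DOCTYPE html><html><head><meta charset='utf-8'>"
           "<title>LSV report</title>"
           "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
           "td,th{border:1px solid #ccc;padding:3px 8px;font-size:90%}</style></head><body>"]
    out.append("<h1>Splice graphs and LSV quantification</h1>")
    out.append("<h2>Groups</h2><table><tr><th>group</th><th>n</th><th>lsv ids</th></tr>")
    for name, ids in groups.items():
        out.append(f"<tr><td>{name}</td><td>{len(ids)}</td>"
                   f"<td>{html.escape(', '.join(ids[:50]))}</td></tr>")
    out.append("</table>")

    for gene_id in sorted(graphs):
        g = graphs[gene_id]
        out.append(f"<h2>{html.escape(gene_id)} ({g.chrom}{g.strand})</h2>")
        out.append(_graph_svg(g))
        for lsv in by_gene.get(gene_id, []):
            out.append(f"<h3>{html.escape(lsv.lsv_id)} "
                       f"<small>{html.escape(classify_lsv(lsv, g))}</small></h3>")
            out.append("<table><tr><th>junction</th>")
            post = psi.get(lsv.lsv_id)
            dpost = dpsi.get(lsv.lsv_id)
            if post is not None:
                out.append("<th>E[&Psi;]</th><th>posterior</th>")
            if dpost is not None:
                out.append("<th>E[&Delta;&Psi;]</th><th>&Delta;&Psi; posterior</th>")
            out.append("</tr>")
            for j, rec in enumerate(lsv.junctions):
                out.append(f"<tr><td>{rec.key.donor_end}-{rec.key.acceptor_start}"
                           f" ({rec.origin})</td>")
                if post is not None:
                    out.append(f"<td>{post.expected_psi[j]:.3f}</td>"
                               f"<td>{_violin_svg(post.masses[j], (0, 1))}</td>")
                if dpost is not None:
                    out.append(f"<td>{dpost.expected_dpsi[j]:+.3f}</td>"
                               f"<td>{_violin_svg(dpost.masses[j], (-1, 1))}</td>")
                out.append("</tr>")
            out.append("</table>")
    out.append("</body></html>")
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# RT-PCR band-intensity PSI
# ---------------------------------------------------------------------------


def rtpcr_psi(
    intensities: Mapping[str, float],
    junction_isoforms: Mapping[str, Iterable[str]],
) -> dict[str, float]:
    """PSI from gel band intensities.

    ``intensities`` maps isoform (band) -> intensity; ``junction_isoforms``
    maps junction -> isoforms containing it.  PSI of a junction is the summed
    intensity of the isoforms including it over the total intensity.
    """
    total = float(sum(intensities.values()))
    if total <= 0:
        raise ValueError("all band intensities are zero; PSI undefined")
    return {
        j: sum(intensities.get(iso, 0.0) for iso in isoforms) / total
        for j, isoforms in junction_isoforms.items()
    }
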