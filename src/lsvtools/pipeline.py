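"""High-level orchestration: build graphs, detect LSVs, quantify PSI/dPSI.

These functions are the library's main entry points; the command-line
interface is a thin wrapper around them.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .annotation_io import GeneModel, JunctionKey, PositionalCounts
from .config import RunConfig
from .lsv import LSV, enumerate_lsvs, filter_existing, filter_quantifiable, remove_redundant
from .quantify import (
    BootstrapSamples,
    DeltaPsiPosterior,
    PsiPosterior,
    bootstrap_rates,
    combine_replicates,
    fit_read_rate_model,
    gc_correct,
    junction_rng,
    psi_posterior,
    zero_samples,
)
from .splicegraph import ReliabilityFilter, SpliceGraph, build_splice_graph

log = logging.getLogger(__name__)

__all__ = ["build", "quantify_psi", "quantify_dpsi", "lsv_footprints"]


def build(
    genes: Sequence[GeneModel],
    evidence: Sequence[PositionalCounts] = (),
    config: RunConfig | None = None,
) -> tuple[dict[str, SpliceGraph], list[LSV]]:
    """Build per-gene splice graphs and the non-redundant existing LSV set."""
    cfg = config or RunConfig()
    filt = ReliabilityFilter(cfg.min_reads, cfg.min_positions)
    graphs: dict[str, SpliceGraph] = {}
    lsvs: list[LSV] = []
    for gene in genes:
        g = build_splice_graph(
            gene, evidence, filt,
            max_denovo_exon=cfg.max_denovo_exon,
            evidence_mode=cfg.evidence_mode,
        )
        graphs[gene.gene_id] = g
        gene_lsvs = remove_redundant(enumerate_lsvs(g))
        gene_lsvs = filter_existing(gene_lsvs, filt, cfg.evidence_mode)
        lsvs.extend(gene_lsvs)
        log.info("%s: %d LSVs retained", gene.gene_id, len(gene_lsvs))
    return graphs, lsvs


def _prepare_experiment(
    counts: Sequence[PositionalCounts],
    experiment_id: str,
    cfg: RunConfig,
    seed: int,
) -> dict[JunctionKey, PositionalCounts]:
    """GC-correct, fit the read-rate model, remove stacks; map by junction."""
    counts = gc_correct(counts, enabled=cfg.gc_correction)
    try:
        _, cleaned = fit_read_rate_model(
            counts, experiment_id, threshold=cfg.stack_pvalue, seed=seed
        )
    except ValueError:  # too little data for a dispersion fit
        cleaned = list(counts)
    return {pc.junction: pc for pc in cleaned}


def _lsv_samples(
    lsv: LSV,
    by_junction: Mapping[JunctionKey, PositionalCounts],
    cfg: RunConfig,
    seed: int,
    stream_tag: str,
) -> list[BootstrapSamples]:
    samples = []
    for j_i, rec in enumerate(lsv.junctions):
        pc = by_junction.get(rec.key)
        rng = junction_rng(seed, lsv.lsv_id, extra=f"{stream_tag}:{j_i}")
        if pc is None or pc.total_reads == 0:
            samples.append(zero_samples(rec.key, cfg.M))
        else:
            samples.append(bootstrap_rates(pc, M=cfg.M, rng=rng))
    return samples


def quantify_psi(
    lsvs: Sequence[LSV],
    replicates: Mapping[str, Sequence[PositionalCounts]],
    config: RunConfig | None = None,
    seed: int | None = None,
) -> list[PsiPosterior]:
    """PSI posteriors for one condition (one or more replicates pooled by
    the conjugate chain rule).  LSVs failing the quantifiable filter in all
    replicates are skipped."""
    from .quantify import combine_group_samples

    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    prepared = {
        exp: _prepare_experiment(counts, exp, cfg, seed)
        for exp, counts in replicates.items()
    }
    out = []
    for lsv in lsvs:
        quant_reps = [
            exp for exp, by_j in prepared.items()
            if filter_quantifiable([lsv], by_j, cfg.quant_min_reads, cfg.quant_min_positions)
        ]
        if not quant_reps:
            continue
        groups = [
            _lsv_samples(lsv, prepared[exp], cfg, seed, stream_tag=exp)
            for exp in sorted(quant_reps)
        ]
        out.append(psi_posterior(lsv.lsv_id, combine_group_samples(groups), cfg.prior()))
    return out


def quantify_dpsi(
    lsvs: Sequence[LSV],
    group_t: Mapping[str, Sequence[PositionalCounts]],
    group_tp: Mapping[str, Sequence[PositionalCounts]],
    config: RunConfig | None = None,
    seed: int | None = None,
) -> list[DeltaPsiPosterior]:
    """dPSI posteriors between two conditions with replicates.

    An LSV must pass the quantifiable filter in at least one replicate of
    *each* condition; otherwise it is excluded with a logged reason.
    """
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    prep_t = {exp: _prepare_experiment(c, exp, cfg, seed) for exp, c in group_t.items()}
    prep_tp = {exp: _prepare_experiment(c, exp, cfg, seed) for exp, c in group_tp.items()}
    out = []
    for lsv in lsvs:
        ok_t = [e for e, b in prep_t.items()
                if filter_quantifiable([lsv], b, cfg.quant_min_reads, cfg.quant_min_positions)]
        ok_tp = [e for e, b in prep_tp.items()
                 if filter_quantifiable([lsv], b, cfg.quant_min_reads, cfg.quant_min_positions)]
        if not ok_t or not ok_tp:
            log.info("%s: quantifiable in only one condition; excluded", lsv.lsv_id)
            continue
        reps_t = [_lsv_samples(lsv, prep_t[e], cfg, seed, stream_tag=f"t:{e}")
                  for e in sorted(ok_t)]
        reps_tp = [_lsv_samples(lsv, prep_tp[e], cfg, seed, stream_tag=f"tp:{e}")
                   for e in sorted(ok_tp)]
        out.append(combine_replicates(lsv.lsv_id, reps_t, reps_tp, cfg.prior()))
    return out


def lsv_footprints(lsvs: Sequence[LSV], graphs: Mapping[str, SpliceGraph]):
    """Exon footprints per lsv_id for overlap filtering of ranked calls."""
    return {l.lsv_id: l.exon_footprint(graphs[l.gene_id]) for l in lsvs}
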