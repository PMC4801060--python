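"""Synthetic gene models and junction read evidence with known ground truth.

The forward model mirrors the quantifier's assumptions: per junction the
total read count is negative-binomial with mean coverage * true_PSI and
dispersion r, spread (near-)uniformly across the read-start window as a
multinomial; occasional single-position read stacks and an optional smooth
GC bias can be injected.  A stated fraction of simulated events is
differential between the two conditions at a stated |dPSI|.

Within a single library, junction totals given the true isoform fractions
are counting noise, hence near-Poisson; the default dispersion r=100 adds
only mild extra-Poisson variability (replicate-to-replicate biological
dispersion enters through independent replicate draws, not through r).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation_io import (
    GeneModel,
    JunctionKey,
    PositionalCounts,
    Transcript,
    write_counts_table,
    write_gff3,
)

__all__ = ["SimTruth", "EventTruth", "simulate_genes", "simulate_counts", "truth_compare"]

EVENT_KINDS = ("cassette", "alt5", "alt3", "multiway")


@dataclass
class EventTruth:
    gene_id: str
    kind: str
    junctions: list[JunctionKey]  # source-LSV junctions, aligned with psi
    psi: dict[str, np.ndarray]  # condition -> true PSI vector (sums to 1)
    differential: bool
    true_dpsi: float
    # junctions of the mirror LSV (e.g. a cassette's target-side inclusion
    # junction) sharing the PSI of the indexed primary junction
    extra_junctions: dict[JunctionKey, int] = field(default_factory=dict)

    def psi_of(self, junction: JunctionKey, condition: str) -> float | None:
        if junction in self.junctions:
            return float(self.psi[condition][self.junctions.index(junction)])
        if junction in self.extra_junctions:
            return float(self.psi[condition][self.extra_junctions[junction]])
        return None

    def to_json(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "kind": self.kind,
            "junctions": [
                [j.chrom, j.strand, j.donor_end, j.acceptor_start] for j in self.junctions
            ],
            "psi": {c: v.tolist() for c, v in self.psi.items()},
            "differential": self.differential,
            "true_dpsi": self.true_dpsi,
        }


@dataclass
class SimTruth:
    genes: list[GeneModel]
    events: list[EventTruth]
    coverage: float = 50.0
    stack_positions: list[tuple[JunctionKey, int]] = field(default_factory=list)
    gc_by_junction: dict[JunctionKey, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coverage": self.coverage,
                    "events": [e.to_json() for e in self.events],
                },
                fh, indent=1,
            )
            fh.write("\n")


def _psi_vector(rng: np.random.Generator, n: int) -> np.ndarray:
    """Realistic baseline PSI: junctions tend to be strongly included or
    excluded (sparse Dirichlet)."""
    v = rng.dirichlet(np.full(n, 0.6))
    return v / v.sum()


def _shift_psi(psi: np.ndarray, dpsi: float, rng: np.random.Generator) -> np.ndarray:
    """Move |dpsi| of mass onto (or off) junction 0, renormalizing the rest."""
    out = psi.copy()
    direction = 1.0 if (psi[0] + dpsi <= 1.0 and (psi[0] + dpsi >= 0.0)) else -1.0
    target = np.clip(psi[0] + direction * dpsi, 0.0, 1.0)
    rest = 1.0 - target
    others = psi[1:]
    out[0] = target
    out[1:] = others / others.sum() * rest if others.sum() > 0 else rest / len(others)
    return out


def simulate_genes(
    n_genes: int,
    seed: int | None = None,
    kind_weights: dict[str, float] | None = None,
    complex_junctions: tuple[int, int] = (3, 6),
    exon_len: int = 150,
    intron_len: int = 1000,
    conditions: Sequence[str] = ("A", "B"),
    diff_fraction: float = 0.2,
    diff_dpsi: float = 0.3,
) -> SimTruth:
    """Generate gene models (one splicing event per gene) with known truth.

    Event kinds: cassette exon, alternative 5'/3' splice site, and multi-way
    splits of 3-6 junctions (complex LSVs).  ``diff_fraction`` of events are
    differential between the first two conditions at |dPSI| = ``diff_dpsi``.
    """
    if n_genes < 1 or exon_len < 10 or intron_len < 100:
        raise ValueError("infeasible structure parameters")
    lo, hi = complex_junctions
    if lo < 3 or hi < lo:
        raise ValueError("complex_junctions must satisfy 3 <= lo <= hi")
    rng = np.random.default_rng(seed)
    weights = kind_weights or {"cassette": 0.4, "alt5": 0.15, "alt3": 0.15, "multiway": 0.3}
    kinds = list(weights)
    p = np.array([weights[k] for k in kinds], dtype=float)
    p /= p.sum()

    models: list[GeneModel] = []
    events: list[EventTruth] = []
    pos = 10_000
    for gi in range(n_genes):
        gene_id = f"simgene{gi:04d}"
        kind = kinds[rng.choice(len(kinds), p=p)]
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = "chrS"
        start = pos
        model, juncs, extras = _make_gene(gene_id, chrom, strand, start, kind,
                                          exon_len, intron_len, rng, (lo, hi))
        pos = model.span[1] + 50_000
        models.append(model)
        psi0 = _psi_vector(rng, len(juncs))
        differential = bool(rng.random() < diff_fraction)
        psi = {}
        for ci, cond in enumerate(conditions):
            if ci == 1 and differential:
                psi[cond] = _shift_psi(psi0, diff_dpsi, rng)
            else:
                psi[cond] = psi0.copy()
        true_d = float(psi[conditions[1]][0] - psi[conditions[0]][0]) if len(conditions) > 1 else 0.0
        events.append(EventTruth(gene_id, kind, juncs, psi, differential, true_d,
                                 extra_junctions=extras))
    return SimTruth(genes=models, events=events)


def _make_gene(gene_id, chrom, strand, start, kind, exon_len, intron_len, rng,
               complex_range) -> tuple[GeneModel, list[JunctionKey], dict[JunctionKey, int]]:
    L, I = exon_len, intron_len
    g = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand)
    extras: dict[JunctionKey, int] = {}

    def exon(i):  # i-th exon slot
        s = start + i * (L + I)
        return (s, s + L)

    if kind == "cassette":
        e1, e2, e3 = exon(0), exon(1), exon(2)
        g.transcripts = [
            Transcript(f"{gene_id}.t1", [e1, e2, e3]),
            Transcript(f"{gene_id}.t2", [e1, e3]),
        ]
        inc1 = JunctionKey(chrom, strand, e1[1], e2[0])
        inc2 = JunctionKey(chrom, strand, e2[1], e3[0])
        skp = JunctionKey(chrom, strand, e1[1], e3[0])
        if strand == "+":
            # source LSV from e1: [inclusion, skip]; target LSV into e3
            # reuses psi[0] for its inclusion junction
            juncs = [inc1, skp]
            extras[inc2] = 0
        else:
            # transcript-upstream exon is e3 on the minus strand
            juncs = [inc2, skp]
            extras[inc1] = 0
    elif kind == "alt5" or kind == "alt3":
        e1, e2 = exon(0), exon(1)
        shift = 60
        if (kind == "alt5") == (strand == "+"):
            # two donor sites on the upstream exon (genomic left)
            alt_e1 = (e1[0], e1[1] - shift)
            g.transcripts = [
                Transcript(f"{gene_id}.t1", [e1, e2]),
                Transcript(f"{gene_id}.t2", [alt_e1, e2]),
            ]
            juncs = [JunctionKey(chrom, strand, e1[1], e2[0]),
                     JunctionKey(chrom, strand, alt_e1[1], e2[0])]
        else:
            alt_e2 = (e2[0] + shift, e2[1])
            g.transcripts = [
                Transcript(f"{gene_id}.t1", [e1, e2]),
                Transcript(f"{gene_id}.t2", [e1, alt_e2]),
            ]
            juncs = [JunctionKey(chrom, strand, e1[1], e2[0]),
                     JunctionKey(chrom, strand, e1[1], alt_e2[0])]
    elif kind == "multiway":
        k = int(rng.integers(complex_range[0], complex_range[1] + 1))
        e1 = exon(0)
        last = exon(k + 1)
        partners = [exon(i + 1) for i in range(k)]
        g.transcripts = [
            Transcript(f"{gene_id}.t{i + 1}", [e1, pe, last])
            for i, pe in enumerate(partners)
        ]
        juncs = [JunctionKey(chrom, strand, e1[1], pe[0]) for pe in partners]
        for i, pe in enumerate(partners):
            extras[JunctionKey(chrom, strand, pe[1], last[0])] = i
    else:
        raise ValueError(f"unknown event kind {kind}")
    return g, juncs, extras


def simulate_counts(
    truth: SimTruth,
    coverage: float = 50.0,
    dispersion_r: float = 100.0,
    stack_rate: float = 0.0,
    stack_size: float = 500.0,
    gc_bias: float = 0.0,
    n_replicates: int = 1,
    n_positions: int = 40,
    positional_alpha: float | None = None,
    seed: int | None = None,
    condition: str = "A",
) -> dict[str, list[PositionalCounts]]:
    """Simulate per-replicate positional junction counts for one condition.

    Per junction the total is NB(mean = coverage * PSI_j, dispersion r)
    spread multinomially across ``n_positions`` read-start offsets, uniform
    by default; a finite ``positional_alpha`` draws Dirichlet position
    probabilities instead (smaller = more positional clumping).  Stacks
    are injected as single-position spikes of
    ``stack_size`` reads at rate ``stack_rate`` per junction.  ``gc_bias``
    scales each junction's mean by exp(gc_bias * (gc - 0.5)) with a
    junction-specific GC drawn uniformly in [0.3, 0.7].

    Returns {replicate_id: [PositionalCounts, ...]}.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    truth.coverage = coverage
    out: dict[str, list[PositionalCounts]] = {}
    # per-junction GC fractions fixed across replicates
    for ev in truth.events:
        for j in list(ev.junctions) + list(ev.extra_junctions):
            if j not in truth.gc_by_junction:
                truth.gc_by_junction[j] = float(rng.uniform(0.3, 0.7))
    for rep in range(n_replicates):
        rep_id = f"{condition}_rep{rep + 1}"
        counts: list[PositionalCounts] = []
        for ev in truth.events:
            psi = ev.psi[condition]
            jpairs = [(j, i) for i, j in enumerate(ev.junctions)]
            jpairs += [(j, i) for j, i in ev.extra_junctions.items()]
            for j, jidx in jpairs:
                gc = truth.gc_by_junction[j]
                mean = coverage * float(psi[jidx]) * float(np.exp(gc_bias * (gc - 0.5)))
                if mean <= 0:
                    total = 0
                else:
                    p = dispersion_r / (dispersion_r + mean)
                    total = int(rng.negative_binomial(dispersion_r, p))
                if positional_alpha is None:
                    probs = np.full(n_positions, 1.0 / n_positions)
                else:
                    probs = rng.dirichlet(np.full(n_positions, positional_alpha))
                vec = rng.multinomial(total, probs) if total > 0 else np.zeros(n_positions, int)
                if stack_rate > 0 and rng.random() < stack_rate:
                    pos_i = int(rng.integers(n_positions))
                    vec[pos_i] += int(stack_size)
                    truth.stack_positions.append((j, pos_i))
                counts.append(
                    PositionalCounts(
                        junction=j,
                        experiment_id=rep_id,
                        counts={int(o): int(c) for o, c in enumerate(vec) if c > 0},
                        gc_fraction=gc,
                    )
                )
        out[rep_id] = counts
    return out


def write_simulation(truth: SimTruth, counts: dict[str, list[PositionalCounts]],
                     outdir: str | Path) -> dict[str, Path]:
    """Write GFF3 + per-replicate counts TSVs + truth manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"gff3": outdir / "genes.gff3", "truth": outdir / "truth.json"}
    write_gff3(truth.genes, paths["gff3"])
    truth.save(paths["truth"])
    for rep_id, pcs in counts.items():
        p = outdir / f"counts_{rep_id}.tsv"
        write_counts_table(pcs, p)
        paths[rep_id] = p
    return paths


def truth_compare(
    estimates: dict[str, np.ndarray],
    truth_psi: dict[str, np.ndarray],
    selected: set[str] | None = None,
    true_differential: set[str] | None = None,
) -> dict:
    """Recovery report: per-event and aggregate |error| of estimated PSI,
    plus a selection confusion matrix when differential calls are given."""
    common = sorted(set(estimates) & set(truth_psi))
    if len(common) != len(estimates) or len(common) != len(truth_psi):
        missing = set(estimates) ^ set(truth_psi)
        raise ValueError(f"estimate/truth id mismatch: {sorted(missing)[:5]} ...")
    errs = {k: np.abs(np.asarray(estimates[k]) - np.asarray(truth_psi[k])) for k in common}
    all_err = np.concatenate([v for v in errs.values()]) if errs else np.zeros(0)
    report = {
        "mae": float(all_err.mean()) if len(all_err) else float("nan"),
        "bias": float(np.mean([np.asarray(estimates[k])[0] - np.asarray(truth_psi[k])[0]
                               for k in common])) if common else float("nan"),
        "per_event_mae": {k: float(v.mean()) for k, v in errs.items()},
        "n": len(common),
    }
    if selected is not None and true_differential is not None:
        ids = set(common)
        tp = len(selected & true_differential & ids)
        fp = len((selected - true_differential) & ids)
        fn = len((true_differential - selected) & ids)
        tn = len(ids) - tp - fp - fn
        report["confusion"] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return report
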