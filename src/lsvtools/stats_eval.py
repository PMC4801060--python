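"""Differential-call selection, reproducibility statistics and enrichment tests.

Differential LSVs are selected by the confidence rule P(|dPSI| > c) > conf
(defaults c=0.2, conf=0.95) and ranked by decreasing |E[dPSI]|.  The
reproducibility ratio RR(n) between two ranked runs is the fraction of the
first n calls of run A that fall inside run B's top N, with N the size of
run A's selected set; it is invariant to permutations of B's top-N order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .quantify import DeltaPsiPosterior, PsiPosterior

log = logging.getLogger(__name__)

__all__ = [
    "RankedCalls",
    "RRCurve",
    "select_differential",
    "overlap_filter",
    "reproducibility_ratio",
    "psi_reproducibility",
    "dominance",
    "max_inclusion_stats",
    "complex_enrichment",
    "permutation_fet",
]


@dataclass
class RankedCalls:
    lsv_ids: list[str]  # ordered by decreasing |E[dPSI]|, ties by lsv_id
    scores: list[float]
    selected_n: int
    footprints: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return self.lsv_ids[: self.selected_n]


@dataclass
class RRCurve:
    values: np.ndarray  # RR(n) for n = 1..N
    N: int


def select_differential(
    posteriors: Sequence[DeltaPsiPosterior],
    dpsi_thresh: float = 0.2,
    confidence: float = 0.95,
    footprints: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> RankedCalls:
    """Rank LSVs by |E[dPSI]| of their most changing junction and select
    those with P(|dPSI| > dpsi_thresh) > confidence for that junction."""
    rows = []
    for post in posteriors:
        j = int(np.argmax(np.abs(post.expected_dpsi)))
        score = float(np.abs(post.expected_dpsi[j]))
        conf = float(post.prob_changing(dpsi_thresh)[j])
        rows.append((post.lsv_id, score, conf))
    rows.sort(key=lambda r: (-r[1], r[0]))
    selected = [r for r in rows if r[2] > confidence]
    fps = {}
    if footprints:
        fps = {lsv_id: sorted(map(tuple, footprints[lsv_id]))
               for lsv_id, _, _ in rows if lsv_id in footprints}
    return RankedCalls(
        lsv_ids=[r[0] for r in rows],
        scores=[r[1] for r in rows],
        selected_n=len(selected),
        footprints=fps,
    )


def _overlaps(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> bool:
    return any(s1 < e2 and s2 < e1 for s1, e1 in a for s2, e2 in b)


def overlap_filter(ranked: RankedCalls) -> RankedCalls:
    """Greedy scan in rank order dropping any LSV whose exons overlap those
    of a higher-ranked retained LSV (conservative de-duplication, e.g. of a
    cassette exon's SS/ST pair)."""
    kept_ids: list[str] = []
    kept_scores: list[float] = []
    kept_fp: list[Sequence[tuple[int, int]]] = []
    n_selected = 0
    for i, (lsv_id, score) in enumerate(zip(ranked.lsv_ids, ranked.scores)):
        fp = ranked.footprints.get(lsv_id, [])
        if any(_overlaps(fp, kfp) for kfp in kept_fp):
            continue
        kept_ids.append(lsv_id)
        kept_scores.append(score)
        kept_fp.append(fp)
        if i < ranked.selected_n:
            n_selected += 1
    return RankedCalls(
        lsv_ids=kept_ids,
        scores=kept_scores,
        selected_n=n_selected,
        footprints={i: ranked.footprints.get(i, []) for i in kept_ids},
    )


def reproducibility_ratio(callsA: RankedCalls, callsB: RankedCalls) -> RRCurve:
    """RR(n) = |top-n of A intersect top-N of B| / n for n = 1..N, with N the
    selected-set size of A (the first argument defines N)."""
    N = callsA.selected_n
    if N == 0:
        log.warning("empty selected set; RR curve is empty")
        return RRCurve(values=np.zeros(0), N=0)
    topB = set(callsB.lsv_ids[:N])
    hits = np.cumsum([1 if x in topB else 0 for x in callsA.lsv_ids[:N]])
    return RRCurve(values=hits / np.arange(1, N + 1), N=N)


def psi_reproducibility(
    psiA: Mapping[str, PsiPosterior], psiB: Mapping[str, PsiPosterior]
) -> dict:
    """Per-junction R = |E[PSI_A] - E[PSI_B]| over LSVs detected in both runs.

    Returns the R values and the fraction reproducible within 5%."""
    rs: list[float] = []
    for lsv_id in sorted(set(psiA) & set(psiB)):
        a, b = psiA[lsv_id], psiB[lsv_id]
        if len(a.expected_psi) != len(b.expected_psi):
            continue
        rs.extend(np.abs(a.expected_psi - b.expected_psi).tolist())
    rs_arr = np.array(rs)
    return {
        "R": rs_arr,
        "fraction_within_5pct": float((rs_arr < 0.05).mean()) if len(rs_arr) else float("nan"),
        "n": len(rs_arr),
    }


def dominance(psi: PsiPosterior, threshold: float = 0.6) -> int | None:
    """Index of the junction with E[PSI] strictly above the threshold, if
    any (at most one can exceed 0.6); None otherwise."""
    above = np.flatnonzero(psi.expected_psi > threshold)
    return int(above[0]) if len(above) else None


def max_inclusion_stats(
    psi_by_condition: Mapping[str, Mapping[str, PsiPosterior]],
) -> dict:
    """Max-across-conditions E[PSI] per junction rank, for CDF summaries.

    Junctions of each LSV are ordered by their maximal E[PSI] across the
    conditions where the LSV was quantified; returns the maxima of the
    2nd/3rd-ranked junctions of complex LSVs and of the least-used junction
    of binary LSVs.
    """
    all_ids: set[str] = set()
    for d in psi_by_condition.values():
        all_ids |= set(d)
    out = {"binary_least": [], "complex_2nd": [], "complex_3rd": [], "complex_least": []}
    for lsv_id in sorted(all_ids):
        posts = [d[lsv_id] for d in psi_by_condition.values() if lsv_id in d]
        if not posts:
            continue
        maxima = np.max([p.expected_psi for p in posts], axis=0)
        ordered = np.sort(maxima)[::-1]
        if len(ordered) == 2:
            out["binary_least"].append(float(ordered[-1]))
        elif len(ordered) > 2:
            out["complex_2nd"].append(float(ordered[1]))
            out["complex_3rd"].append(float(ordered[2]) if len(ordered) > 2 else float("nan"))
            out["complex_least"].append(float(ordered[-1]))
    return {k: np.array(v) for k, v in out.items()}


def complex_enrichment(
    n_complex_changing: int,
    n_changing: int,
    n_complex_detected: int,
    n_detected: int,
    n_datasets: int = 1,
) -> dict:
    """Fold enrichment of complex LSVs among changing vs detected LSVs, with
    a one-sided binomial tail p and Bonferroni correction across datasets."""
    if n_changing == 0:
        return {"fold": float("nan"), "p": float("nan"), "p_bonferroni": float("nan"),
                "applicable": False}
    if n_detected == 0:
        raise ValueError("empty detected set")
    background = n_complex_detected / n_detected
    if background == 0:
        if n_complex_changing > 0:
            raise ValueError("background complex proportion is 0: invalid null")
        return {"fold": float("nan"), "p": 1.0, "p_bonferroni": 1.0, "applicable": False}
    fold = (n_complex_changing / n_changing) / background
    p = float(stats.binom.sf(n_complex_changing - 1, n_changing, background))
    return {
        "fold": fold,
        "p": p,
        "p_bonferroni": min(1.0, p * n_datasets),
        "applicable": True,
    }


def permutation_fet(
    table,
    n_perm: int = 10_000,
    seed: int | None = None,
    correction: str = "min_p",
) -> "pd.DataFrame":
    """LSV-origin-controlled permutation correction of per-feature Fisher tests.

    ``table`` is a DataFrame with columns ``lsv_id``, ``label`` (binary group)
    and one boolean column per feature.  Raw p per feature comes from the 2x2
    Fisher exact test of feature vs label.  The null shuffles labels between
    junctions of LSVs with the same junction count (whole-LSV label blocks
    are swapped between same-size LSVs), preserving the per-LSV label
    multiset, the group sizes, and within-LSV feature correlation.  The
    corrected p is the fraction of permutations whose minimum raw p across
    features is <= the observed raw p (family-wise ``min_p`` convention;
    ``correction='per_feature'`` uses each feature's own permutation null).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    feats = [c for c in table.columns if c not in ("lsv_id", "label")]
    usable = [f for f in feats if table[f].sum() >= 2]
    for f in feats:
        if f not in usable:
            log.info("feature %s present in <2 junctions; excluded", f)
    labels = np.asarray(table["label"].values).astype(bool)
    fmat = table[usable].values.astype(bool)

    def fisher_ps(lab: np.ndarray) -> np.ndarray:
        ps = np.empty(len(usable))
        for i in range(len(usable)):
            f = fmat[:, i]
            t = [[int((f & lab).sum()), int((f & ~lab).sum())],
                 [int((~f & lab).sum()), int((~f & ~lab).sum())]]
            ps[i] = stats.fisher_exact(t)[1]
        return ps

    obs = fisher_ps(labels)

    # group LSVs by junction count for the controlled shuffle
    lsv_rows: dict[str, np.ndarray] = {
        lsv: np.flatnonzero(table["lsv_id"].values == lsv)
        for lsv in pd.unique(table["lsv_id"])
    }
    by_size: dict[int, list[str]] = {}
    for lsv, rows in lsv_rows.items():
        by_size.setdefault(len(rows), []).append(lsv)

    null_ps = np.empty((n_perm, len(usable)))
    for p_i in range(n_perm):
        lab = labels.copy()
        for size, lsvs in by_size.items():
            perm = rng.permutation(len(lsvs))
            src = np.concatenate([lsv_rows[lsvs[k]] for k in range(len(lsvs))])
            dst = np.concatenate([lsv_rows[lsvs[k]] for k in perm])
            lab[dst] = labels[src]
        null_ps[p_i] = fisher_ps(lab)

    if correction == "min_p":
        min_null = null_ps.min(axis=1)
        corrected = [(min_null <= o).mean() for o in obs]
    else:
        corrected = [(null_ps[:, i] <= obs[i]).mean() for i in range(len(usable))]
    return pd.DataFrame({"feature": usable, "p_raw": obs, "p_corrected": corrected})
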