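# Methods

This note documents the models, defaults, and numerical choices behind
`lsvtools`, and what the simulation-based tests do and do not demonstrate.

## Coordinates and junction identity

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the parse/write boundary and round-trips exactly.
A junction is keyed genomically by `(chrom, strand, donor_end,
acceptor_start)` — `donor_end` is the half-open end of the upstream exonic
segment. Strand affects only 5'/3' labelling and transcript-orientation
ordering (LSV direction, type strings), never the key, because BAM evidence
is genomic. "Uniquely mapped" is a configurable MAPQ threshold (default 255,
the convention where the aligner reserves the maximum for unique hits).

## Splice-graph construction

Annotated exons are merged per gene into maximal exonic segments; annotated
junctions are kept even with zero reads. A de novo junction needs the
reliability filter (defaults: ≥2 reads from ≥2 distinct start positions) in
at least one experiment (`evidence_mode="any"`; `"all"` requires every
experiment). De novo splice sites landing outside exons are resolved by
splice-site orientation: a novel acceptor opens exonic sequence and so
extends the *downstream* exon's start; a novel donor extends the *upstream*
exon's end; an acceptor followed by a donor within one intron delimits a
putative de novo exon. Any de novo exonic region longer than
`max_denovo_exon` (500 bp, roughly the upper tail of known exon lengths)
becomes an open-ended region: retained in the graph and reports, excluded
from LSV enumeration because its far boundary carries no splice-site
identity.

Intron retention: the intron between two adjacent closed exons gains a
retention edge iff *every* 50 bp window tiled across it (last window
truncated; sub-window introns are one window) has mean coverage ≥
`min_intronic_cov` in ≥1 experiment. The builder default is 1.5; a relaxed
0.5 setting is the same parameter and is useful when coverage is shallow —
the strict-all-windows reading makes the call monotone in the threshold.

## LSV enumeration and canonicalization

Each exon with ≥2 outgoing (transcript orientation) edges yields a
single-source LSV; ≥2 incoming edges a single-target LSV. Retention edges
count as junctions on both flanking exons. Junctions are ordered by
reference-exon splice site then partner coordinate in strand-aware
orientation, which makes type strings (`s|1e1.1|1e2.1` and the like)
identical for mirror-image structures on opposite strands. Redundancy
removal drops any LSV whose edge set is a strict subset of a retained LSV's
edge set; equal edge sets keep the single-source member (an arbitrary but
deterministic tie-break). LSVs whose reference exon is itself de novo are
admitted and flagged `has_denovo`.

Existence filter (builder): all junctions reliable, and ≥1 junction with
read support at the reliability thresholds. Quantifiability filter
(quantifier): ≥1 junction with ≥10 reads from ≥3 positions, applied to
post-stack-removal counts so stacks cannot qualify an LSV.

## Read-rate model

- **Dispersion.** A single zero-truncated negative-binomial dispersion `r`
  per experiment, fitted by 1-D maximum likelihood over the nonzero position
  counts of up to 10,000 junctions (each junction's mean is its plug-in
  nonzero-position sample mean). The optimum is clamped to [0.01, 1e4];
  degenerate (variability-free) data returns the cap with a warning. The
  plug-in mean slightly overstates low means under truncation; at the
  read depths where quantification happens this bias is negligible, and the
  parameter-recovery test (true r = 5, mean 20) bounds the total error.
- **Stacks.** For each nonzero position, the NB upper tail of its count
  given `r` and the mean of the junction's *other* nonzero positions;
  p ≤ 1e-7 flags the position and removes its reads everywhere downstream.
  A single-position junction is untestable and kept.
- **Bootstrap.** Relevant positions are the nonzero, non-stack read-start
  positions (W of them). Each of M = 100 samples draws W positions with
  replacement and reports μ = W · (sample mean), i.e. a resampled total.
  An alternate mode takes W from the mappable window instead; the default
  follows the observed-nonzero reading. Per-LSV random streams are derived
  by hashing the LSV id with the run seed (CRC32 into a SeedSequence), so
  results are independent of iteration order and parallel scheduling.

## Posterior inference

Marginal Ψ posteriors per junction: conjugate Beta(η/J + μ_j,
η(J−1)/J + Σ_{k≠j} μ_k) per bootstrap sample, discretized by exact
regularized-incomplete-beta differences on the V = 40 grid and averaged
over samples. Reported E[Ψ] averages the *analytic* Beta means, so
Σ_j E[Ψ_j] = 1 to machine precision. A junction with zero surviving reads
is shaped by the prior pseudo-counts alone; an all-zero LSV returns the
discretized prior flagged low-confidence.

ΔΨ: per sample, the two conditions' posteriors multiply on the
(Ψ_t, Ψ_t′) grid with the ΔΨ prior factor, normalize, and marginalize onto
the 2V−1 difference bins (centres k/V). Two numerical points matter:

- The ΔΨ mixture's spike component is narrower than one grid bin, so
  evaluating its density at bin centres misintegrates it. The factor is
  instead the mixture density convolved with the triangular kernel implied
  by uniform-within-bin marginals, by trapezoidal quadrature.
- The joint is computed on an internally refined grid (`refine` = 4, i.e.
  160 bins) and aggregated to the output grid. The refined joint
  factorizes by within-cell offset, giving an O(M·V²·refine) einsum
  instead of a dense (V·refine)² grid. Against dense fine-grid integration
  (V_f = 2000–4000) the discretized posteriors agree within total
  variation ~3e-4 for quantifiable read depths (the test bound is 1e-3).

Replicates pool by the Beta chain rule — equivalent to summing the
per-replicate sampled read rates before a single conjugate update; sample
m of each replicate is paired. Swapping conditions mirrors the posterior
exactly; identical inputs centre it at 0.

Prior defaults: η = 1 (Jeffreys for J = 2, encouraging high inclusion or
exclusion, as empirical Ψ distributions warrant); mixture weights
(0.2, 0.3, 0.5) over spike Beta(1500, 1500), perturbation Beta(75, 75) and
uniform Beta(1, 1) on the (ΔΨ+1)/2 scale. The mixture shape is a design
choice of this package (visibly trimodal in width, configurable); the
spike's sd (~0.018 in ΔΨ) keeps null fluctuations from crossing the 0.2
selection threshold while leaving |ΔΨ| ≈ 0.3 signals essentially unshrunk
(measured shrinkage ≈ 0.01 at coverage 150). On fixed data the
spike-containing prior never yields larger |E[ΔΨ]| than the uniform slab —
the regularization only shrinks.

`P(|ΔΨ| > c)` sums bins with |centre| strictly above c; selection uses the
defaults c = 0.2, confidence 0.95, both configurable (relaxed 0.15/0.10
modes included). Ranking is by |E[ΔΨ]| with lexicographic id tie-break;
the selected set is the top-N ranking prefix with N set by the confidence
rule. Dominance uses strict E[Ψ] > 0.6. For RR between two runs, the first
argument's selected-set size defines N.

## Simulator

The generator emulates exactly what the quantifier assumes: per junction,
total reads ~ NB(mean = coverage·Ψ_j, dispersion r) spread multinomially
over 40 read-start positions (uniform by default; Dirichlet clumping,
stacks, and an exponential GC-bias factor are available and off by
default). Defaults: coverage 50, r = 100, 20 % of events differential at
|ΔΨ| = 0.3. The dispersion default reflects that within a single library,
junction totals given the true isoform fractions are counting noise —
near-Poisson with mild extra variation; replicate-level biological
overdispersion enters through independent replicate draws instead. Complex
events span 3–6 junctions.

What the simulations do **not** capture: mappability structure and
alignment artefacts along the junction window, correlated GC/positional
biases, shared junctions between overlapping genes, partially degraded
RNA, and isoform-level (rather than junction-level) coupling of counts.
Recovery results on these simulations therefore demonstrate correctness of
the inference machinery under its own model, not end-to-end accuracy on
real libraries.

## Benchmark problem sizes

The evaluation studies are sized for a desk-scale run: Ψ recovery on 250
cassette genes (~500 binary LSVs, truth on a 19-point grid, coverage 50,
MAE ≈ 0.046–0.05); ΔΨ recovery on 100 genes (200 LSVs, 3-vs-3 replicates,
|ΔΨ| = 0.3; per-LSV error sd ≈ 0.06, so the fraction within 0.1 of truth
sits near 0.90 and varies by a few percent across seeds); null calibration
on 250 genes (selection rate ~0 under the spike prior, far below the 5 %
bound); ZTNB recovery on 1000 junctions (relative error ≈ 2–3 %). The
whole suite runs in a few minutes on one CPU.

## Known limitations

- The builder trusts the annotation's exon boundaries; it does not infer
  novel transcription starts/ends beyond open-ended flags.
- GC correction is a deliberately simple smooth-factor rescaling (quadratic
  in GC on the log scale, normalized to mean 1), off by default; it removes
  monotone trends but not fragment-level interactions.
- Intron-retention quantification treats the retention edge as one
  junction without positional counts of its own, so its posterior is
  driven by the flanking junctions' evidence and the prior.
- The HTML report is static by design; grouping tables replace interactive
  filtering.
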