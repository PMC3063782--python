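# Methods

## The model

The pipeline targets the canonical signal of an activating promoter histone
mark measured by ChIP-seq with single-end 36-nt tags. In TSS-relative,
transcription-oriented coordinates, tag density over a gene is modelled as a
uniform genomic background plus two Gaussian components: a smaller pre-TSS
component and a dominant post-TSS component, separated by a depleted zone
just upstream of the TSS (the nucleosome-free region). Treatment acts in two
ways: the post-TSS component broadens, and selected (induced) genes receive
a per-gene enrichment multiplier. Expression is modelled per gene as a
Poisson read count with mean

    E[count] = baseline_RPKM × fold × exon_kb × library_size / 10⁶,

with fold > 1 planted only for induced genes under the treated condition.

## Synthetic-data generator

`promark.simulate` draws exactly `n_tags` tags from the mixture. The
background mixture weight is `background_rate × genome_bp`; each Gaussian
component of amplitude *A* (peak density as fold over background),
multiplier *m* and width σ carries weight `(A−1) · m · background_rate ·
σ·√(2π)`, so its modal density is *A·m*-fold over background. Component
draws landing inside the depletion zone are redrawn. Defaults (all
config-exposed):

| parameter | default | meaning |
|---|---|---|
| background_rate | 0.02 /bp | uniform background weight |
| pre_tss_mode / pre_width / pre_amplitude | −250 bp / 100 bp / 4× | pre-TSS component |
| dip_offset / dip_halfwidth | −100 bp / 100 bp | depletion zone [−200, 0) |
| post_tss_mode / post_amplitude | +400 bp / 8× | post-TSS component |
| post_width control → treated | 300 → 500 bp | treatment broadening |
| read length | 36 bp | single-end tag length |

The default genome is 200 non-overlapping genes (2–20 kb, 1–5 exons, both
strands) on one 20 Mb chromosome; the default ChIP library is 430,000 tags
against a 400,000-tag background-only input, giving roughly two input tags
per 100 bp window and an expected ~105 post-TSS plus ~23 pre-TSS component
tags per gene — i.e. well-powered but not trivial peak calling. The
qualitative landmarks (mode positions, the dip, treatment broadening) match
what the analysis is designed to detect; the quantitative rates are the
package's own choice, since no public raw data fixes them.

The dip is produced by an explicit exclusion zone rather than by mode
separation alone: with a pre mode at −250 and a post mode at +400, the sum
of two Gaussians has its minimum near the weighted midpoint, not at −100,
so pure mode separation cannot reproduce the stated dip position.

What the generator does **not** emulate: sequence content (no FASTQ, no
aligner, no mappability structure), fragment-length variation (tags are
placed at their 5′ ends; fragment extension exists but defaults to off),
spliced RNA reads (simulated reads truncate at exon boundaries), overdispersed
expression counts (Poisson, not negative binomial), and copy-number or
GC biases in the input. Passing tests therefore demonstrate correctness of
the analysis logic under the planted model, not robustness to every artifact
of real libraries.

## Tag processing

Records with `start ≥ end` are rejected per record; non-unique alignments
are removed; duplicates are collapsed on (chromosome, 5′ position, strand) —
position-level, the standard tag-library convention, since sequence-level
identity is unavailable after reduction to intervals. Depth normalization
sub-samples the larger library uniformly without replacement to the size of
the smaller, pairwise per comparison (each ChIP library vs its input; the
treated vs control pair is matched separately before fold-change
re-tallying).

## Peak caller

Windowing assigns each tag to the 100 bp window containing its strand-aware
5′ position. The per-window test is a one-sided Poisson tail
`P(X ≥ t)` with `λ = max(scaled input count, global floor)`, the floor being
the scaled genome-wide mean input count per window — this guards
zero-input windows without a MACS-style local-λ model, which this caller
deliberately omits. Significant windows (p < 0.05, ≥1 tag) separated by at most one
window-width (at most one intervening window) consolidate into candidates;
region qualification applies the tag-count (≥40 raw post-subsampling tags),
log2-ratio (≥1, pseudocount 1 on both sides) and region-level Poisson gates.
P-values are deliberately **not** multiple-testing corrected: the raw
p < 0.05 gate operates jointly with the other gates, and overall error is
quantified empirically by the sample swap, whose output (swapped/forward
peak counts) is exactly a per-dataset global FDR. Under the default
scenario this swap FDR measures 0 of ~230 forward peaks per replicate.

Degenerate inputs: an empty treatment library returns no peaks; an empty or
zero-length genome raises; tags outside declared chromosome bounds are
rejected and counted.

## Peak comparison and TSS annotation

Matching chains peaks across conditions transitively at a 1 bp overlap
threshold; output regions are disjoint and cover exactly the union of the
inputs, so the region count is the "combined" count. Fold change is
re-tallied from tags over the union region — not derived from peak scores —
so single-sided regions get finite folds in both directions (a
treated-only region with 80 tags and empty control gives (80+1)/(0+1) = 81;
a control-only region gives a fold below 1). A region annotates to every
gene whose TSS ± span (default 5,000 bp) window it overlaps; the reported
distance runs from the TSS to the nearest region edge, signed positive
downstream of transcription; per gene only the highest-fold within-span
region is kept.

## RNA quantification

Gene models use the exon union; a read counts for a gene iff its interval
overlaps that union, reads overlapping exons of two or more genes are
discarded as ambiguous (tallied, so counts + discards = input). RPKM counts
*reads*, following the normalization as originally defined, although the
summary percentages helper rounds half-up to the nearest integer. Fold
induction is `RPKM_t / (RPKM_c + pseudo)` with pseudo = the RPKM of one
control read, keeping zero-control folds finite while leaving well-covered
genes essentially unbiased. The "induced" flag threshold defaults to fold
≥ 2.0 — an assumption, config-exposed, as no principled cutoff exists for
plain ratios. Within the pipeline, RPKM for both conditions is normalized
by the nominal sequencing depth rather than the realized count sum: the
simulator models absolute per-gene rates at a fixed depth, and realized-sum
normalization would re-introduce the usual composition bias (induced genes'
extra reads deflate every other gene's RPKM), which is a property of the
estimator, not of the planted truth. The file-based `quantify` subcommand,
where nominal depth is unknown, normalizes by the realized total.

## Metagene profiles

Profiles accumulate base pairs of tag–bin intersection (not tag counts),
per 100 bp bin over TSS ± 5,000 bp, strand-oriented by default (without
orientation, − strand genes would mirror and smear the +400 post-TSS
structure). Aggregation is a plain sum over the gene set with `n_genes`
recorded — for a fixed set, sum and mean differ only by a constant factor.
Conservation is exact by construction: Σ bins = Σ tag∩window. Width
comparisons use the contiguous run of bins ≥ half the profile maximum,
which is scale-invariant and robust to distant secondary bumps.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; windows and peak boundaries
  are window-aligned; interval overlap everywhere means ≥ 1 shared base.
- All generators are pure functions of (spec, seed); pipeline stages derive
  per-stage seeds from the single run seed via a seed sequence, and reports
  are byte-identical across same-seed runs.
- Induction ranking breaks fold ties by gene name for a deterministic total
  order.
- Matched regions hold tuples of contributing peaks per side, since
  transitive chaining can place several same-condition peaks in one region.
- Percentages round half-up; where rounding conventions genuinely collide
  (x.5-adjacent cases), the helper's behaviour is fixed and documented
  rather than locale-dependent.

## Problem sizes used by the test-suite and benchmark

The acceptance-style checks run the default 20 Mb / 200-gene scenario for
the swap-FDR benchmark (20 replicates) and caller sensitivity (3
replicates), a 5 Mb / 50-gene scenario at 120k tags per library for the
metagene landmark recovery (20 replicates), and count-level RNA recovery at
10 M nominal depth; brute-force oracle comparisons use ≤ 10 kb genomes and
≤ 5,000 tags, where exhaustive per-window and per-base loops stay exact and
fast. These sizes are the package's chosen desk-scale defaults; all are
config-exposed.

## Known limitations

- The caller has no local background model (input λ is window-wise or
  global-floor), no fragment-shift model, and no per-peak q-values — the
  sample swap gives one global FDR per dataset.
- Fold changes carry no significance statistics; they are plain ratios.
- Expression folds estimated from RPKM ratios are biased toward 1 by the
  pseudo floor for genes with very low control expression (a planted 54.64
  at control RPKM 2 reads back ≈ 52 at high depth, lower still at reduced
  depth).
- Multi-isoform genes must be resolved to one TSS and one exon union in the
  input gene table; the package does not select among isoforms.
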