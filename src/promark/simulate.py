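"""Synthetic genomes, ChIP tag libraries, and RNA-seq read counts.

The generator plants the promoter enrichment architecture that the analysis
is built to detect: over a uniform genomic background, each gene receives two
Gaussian enrichment components in TSS-relative, transcription-oriented
coordinates — a smaller pre-TSS component and a dominant post-TSS component
(default mode +400 bp) — separated by an explicit depletion zone around
-100 bp where component draws are excluded, emulating the nucleosome-free
region upstream of the first transcribed nucleosome. Under "treated"
conditions the post-TSS component broadens and selected genes receive a
per-gene enrichment multiplier, reproducing the higher-and-broader downstream
signal seen for strongly induced genes.

RNA-seq is simulated at the count level (Poisson around an RPKM-derived
expectation) and optionally materialized as exonic reads, with configurable
per-gene fold inductions.

Every generator is a pure function of its spec and seed; the number of tags
emitted equals the number requested exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genes import GeneModel
from .tags import Tag

_SQRT_2PI = math.sqrt(2.0 * math.pi)

DEFAULT_READ_LENGTH = 36  # single-end 36-nt tags


class GenomeSizingError(ValueError):
    """Requested genes do not fit on the given chromosomes."""


@dataclass
class SyntheticGenomeSpec:
    """Layout of a synthetic genome: chromosome sizes and gene placement rules."""

    chrom_sizes: dict[str, int]
    n_genes: int = 200
    min_gene_length: int = 2_000
    max_gene_length: int = 20_000
    intergenic_gap_min: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_sizes or any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("chrom_sizes must be non-empty with positive lengths")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0 < self.min_gene_length <= self.max_gene_length:
            raise ValueError("need 0 < min_gene_length <= max_gene_length")
        if self.intergenic_gap_min < 0:
            raise ValueError("intergenic_gap_min must be >= 0")

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class EnrichmentArchitecture:
    """TSS-relative enrichment mixture planted in ChIP libraries.

    Offsets are signed base pairs from the TSS in the direction of
    transcription. Amplitudes are peak densities as fold over the uniform
    background (amplitude 1 means no enrichment); widths are Gaussian sigmas.
    ``multipliers`` scales both components per gene, applied only under the
    "treated" condition, and the post-TSS component widens from
    ``post_width_control`` to ``post_width_treated``.
    """

    background_rate: float = 0.02  # tags per bp (mixture weight scale)
    pre_tss_mode: int = -250
    pre_width: float = 100.0
    pre_amplitude: float = 4.0
    dip_offset: int = -100
    dip_halfwidth: int = 100
    post_tss_mode: int = 400
    post_width_control: float = 300.0
    post_width_treated: float = 500.0
    post_amplitude: float = 8.0
    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if self.pre_amplitude < 1 or self.post_amplitude < 1:
            raise ValueError("amplitudes must be >= 1 (fold over background)")
        if min(self.pre_width, self.post_width_control, self.post_width_treated) <= 0:
            raise ValueError("component widths must be > 0")
        if not self.pre_tss_mode < self.dip_offset < self.post_tss_mode:
            raise ValueError("dip_offset must lie between the pre- and post-TSS modes")
        if self.dip_halfwidth < 0:
            raise ValueError("dip_halfwidth must be >= 0")

    def post_width(self, condition: str) -> float:
        return self.post_width_treated if condition == "treated" else self.post_width_control

    def multiplier(self, gene: str, condition: str) -> float:
        return self.multipliers.get(gene, 1.0) if condition == "treated" else 1.0


@dataclass
class ExpressionSpec:
    """Per-gene baseline expression and planted fold inductions."""

    baseline_rpkm: dict[str, float]
    fold_induction: dict[str, float] = field(default_factory=dict)
    library_size: int = 10_000_000
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.baseline_rpkm.values()):
            raise ValueError("baseline RPKM values must be >= 0")
        if any(v < 0 for v in self.fold_induction.values()):
            raise ValueError("fold inductions must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")


# ---------------------------------------------------------------------------
# Gene placement


def make_gene_models(spec: SyntheticGenomeSpec) -> list[GeneModel]:
    """Place non-overlapping genes on the synthetic genome.

    Genes are assigned to chromosomes proportionally to length, laid out left
    to right with at least ``intergenic_gap_min`` bp between neighbours and
    uniformly distributed slack, given random strands and 1–5 exons spanning
    the transcript. Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_genes == 0:
        return []

    chroms = list(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    assignment = rng.choice(len(chroms), size=spec.n_genes, p=sizes / sizes.sum())

    genes: list[GeneModel] = []
    idx = 0
    for ci, chrom in enumerate(chroms):
        n_here = int(np.sum(assignment == ci))
        if n_here == 0:
            continue
        size = spec.chrom_sizes[chrom]
        lengths = rng.integers(spec.min_gene_length, spec.max_gene_length + 1, size=n_here)
        required = int(lengths.sum()) + (n_here + 1) * spec.intergenic_gap_min
        if required > size:
            raise GenomeSizingError(
                f"chromosome {chrom} ({size} bp) too small for {n_here} genes "
                f"(needs >= {required} bp)"
            )
        slack = size - required
        # split the slack into n_here+1 ordered chunks
        cuts = np.sort(rng.integers(0, slack + 1, size=n_here))
        extra = np.diff(np.concatenate(([0], cuts)))
        pos = spec.intergenic_gap_min
        for j in range(n_here):
            pos += int(extra[j])
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    name=f"gene{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=_random_exons(rng, start, end),
                )
            )
            idx += 1
            pos = end + spec.intergenic_gap_min
    return genes


def _random_exons(
    rng: np.random.Generator, start: int, end: int
) -> tuple[tuple[int, int], ...]:
    """1–5 exons covering the transcript ends, split by random internal cuts."""
    length = end - start
    k = int(rng.integers(1, 6))
    k = min(k, (length + 1) // 2)
    if k == 1:
        return ((start, end),)
    n_cuts = 2 * k - 2
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False))
    bounds = [start] + [start + int(c) for c in cuts] + [end]
    return tuple((bounds[i], bounds[i + 1]) for i in range(0, 2 * k - 1, 2))


# ---------------------------------------------------------------------------
# ChIP tag simulation


def simulate_chip_tags(
    genes: Sequence[GeneModel],
    arch: EnrichmentArchitecture,
    n_tags: int,
    seed: int,
    *,
    chrom_sizes: Mapping[str, int],
    condition: str = "control",
    read_length: int = DEFAULT_READ_LENGTH,
    duplicate_fraction: float = 0.0,
    multi_fraction: float = 0.0,
) -> list[Tag]:
    """Draw ChIP tags from uniform background plus per-gene TSS components.

    The mixture weight of the background is ``background_rate × genome_bp``;
    each Gaussian component contributes ``(amplitude−1) × multiplier ×
    background_rate × width × √(2π)`` so that its peak density is
    ``amplitude × multiplier`` fold over background. Component draws landing
    in the depletion zone are redrawn, carving the planted dip. Exactly
    ``n_tags`` tags are returned, coordinate-sorted. ``multi_fraction`` of
    tags are flagged non-unique and ``duplicate_fraction`` are replaced by
    copies of other tags, to exercise upstream filtering.
    """
    if n_tags < 0:
        raise ValueError("n_tags must be >= 0")
    if n_tags == 0:
        return []
    if condition not in ("control", "treated"):
        raise ValueError(f"condition must be 'control' or 'treated', got {condition!r}")
    rng = np.random.default_rng(seed)

    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    genome_bp = float(sizes.sum())
    if genome_bp <= 0:
        raise ValueError("genome has zero length")

    post_w = arch.post_width(condition)
    weights = [arch.background_rate * genome_bp]
    comps: list[tuple[GeneModel, int, float]] = []  # (gene, mode, width)
    for g in genes:
        m = arch.multiplier(g.name, condition)
        w_pre = (arch.pre_amplitude - 1.0) * m * arch.background_rate * arch.pre_width * _SQRT_2PI
        w_post = (arch.post_amplitude - 1.0) * m * arch.background_rate * post_w * _SQRT_2PI
        if w_pre > 0:
            weights.append(w_pre)
            comps.append((g, arch.pre_tss_mode, arch.pre_width))
        if w_post > 0:
            weights.append(w_post)
            comps.append((g, arch.post_tss_mode, post_w))
    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(n_tags, probs)

    chrom_arr: list[str] = []
    pos_list: list[np.ndarray] = []

    # background: chromosome by length, position uniform
    n_bg = int(counts[0])
    if n_bg:
        bg_chrom = rng.choice(len(chroms), size=n_bg, p=sizes / genome_bp)
        bg_pos = rng.integers(0, sizes[bg_chrom].astype(np.int64))
        chrom_arr.extend(chroms[i] for i in bg_chrom)
        pos_list.append(bg_pos)

    dip_lo = arch.dip_offset - arch.dip_halfwidth
    dip_hi = arch.dip_offset + arch.dip_halfwidth
    for (g, mode, width), n in zip(comps, counts[1:]):
        n = int(n)
        if n == 0:
            continue
        offs = rng.normal(mode, width, size=n)
        if arch.dip_halfwidth > 0:
            for _ in range(100):
                bad = (offs >= dip_lo) & (offs < dip_hi)
                if not bad.any():
                    break
                offs[bad] = rng.normal(mode, width, size=int(bad.sum()))
        offs = np.rint(offs).astype(np.int64)
        pos = g.tss + offs if g.strand == "+" else g.tss - offs
        chrom_arr.extend([g.chrom] * n)
        pos_list.append(pos)

    pos = np.concatenate(pos_list)
    size_by_chrom = np.array([chrom_sizes[c] for c in chrom_arr], dtype=np.int64)
    pos = np.clip(pos, read_length, size_by_chrom - read_length - 1)
    strands = np.where(rng.random(n_tags) < 0.5, "+", "-")

    out: list[Tag] = []
    for c, p, s in zip(chrom_arr, pos, strands):
        p = int(p)
        if s == "+":
            out.append(Tag(c, p, p + read_length, "+"))
        else:
            out.append(Tag(c, p + 1 - read_length, p + 1, "-"))

    n_multi = int(round(multi_fraction * n_tags))
    n_dup = int(round(duplicate_fraction * n_tags))
    if n_multi or n_dup:
        perm = rng.permutation(n_tags)
        for i in perm[:n_multi]:
            t = out[i]
            out[i] = dataclasses.replace(t, unique=False)
        if n_dup:
            targets = perm[n_multi : n_multi + n_dup]
            sources = rng.choice(np.delete(np.arange(n_tags), targets), size=len(targets))
            for t_i, s_i in zip(targets, sources):
                out[t_i] = out[s_i]

    out.sort(key=lambda t: (t.chrom, t.start, t.end, t.strand))
    return out


def simulate_input_tags(
    genes: Sequence[GeneModel],
    background_rate: float,
    n_tags: int,
    seed: int,
    *,
    chrom_sizes: Mapping[str, int],
    read_length: int = DEFAULT_READ_LENGTH,
    duplicate_fraction: float = 0.0,
    multi_fraction: float = 0.0,
) -> list[Tag]:
    """Background-only library: input chromatin with no immunoprecipitation."""
    arch = EnrichmentArchitecture(
        background_rate=background_rate, pre_amplitude=1.0, post_amplitude=1.0
    )
    return simulate_chip_tags(
        genes,
        arch,
        n_tags,
        seed,
        chrom_sizes=chrom_sizes,
        read_length=read_length,
        duplicate_fraction=duplicate_fraction,
        multi_fraction=multi_fraction,
    )


# ---------------------------------------------------------------------------
# RNA-seq simulation


def expected_rna_count(gene: GeneModel, expr: ExpressionSpec, condition: str) -> float:
    """Expected read count: baseline RPKM × fold × exon kb × library millions."""
    base = expr.baseline_rpkm.get(gene.name, 0.0)
    fold = expr.fold_induction.get(gene.name, 1.0) if condition == "treated" else 1.0
    return base * fold * (gene.exon_model_length / 1000.0) * (expr.library_size / 1e6)


def simulate_rna_counts(
    genes: Sequence[GeneModel], expr: ExpressionSpec, condition: str
) -> dict[str, int]:
    """Poisson per-gene read counts around the RPKM-derived expectation."""
    if condition not in ("control", "treated"):
        raise ValueError(f"condition must be 'control' or 'treated', got {condition!r}")
    known = {g.name for g in genes}
    missing = (set(expr.baseline_rpkm) | set(expr.fold_induction)) - known
    if missing:
        raise ValueError(f"expression spec names unknown genes: {sorted(missing)[:5]}")
    rng = np.random.default_rng([expr.seed, 0 if condition == "control" else 1])
    return {
        g.name: int(rng.poisson(expected_rna_count(g, expr, condition))) for g in genes
    }


def simulate_rna_reads(
    genes: Sequence[GeneModel],
    expr: ExpressionSpec,
    condition: str,
    counts: Mapping[str, int] | None = None,
) -> list[Tag]:
    """Materialize simulated counts as exonic reads (one Tag per counted read).

    Read starts are uniform over each gene's exon model; a read is truncated
    at its exon boundary rather than spliced, which is adequate for
    exon-overlap counting.
    """
    if counts is None:
        counts = simulate_rna_counts(genes, expr, condition)
    rng = np.random.default_rng([expr.seed, 2 if condition == "control" else 3])
    reads: list[Tag] = []
    for g in genes:
        n = int(counts.get(g.name, 0))
        if n == 0:
            continue
        exon_lens = np.array([e - s for s, e in g.exons], dtype=float)
        which = rng.choice(len(g.exons), size=n, p=exon_lens / exon_lens.sum())
        for ei in which:
            s, e = g.exons[int(ei)]
            start = int(rng.integers(s, e))
            end = min(start + expr.read_length, e)
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(Tag(g.chrom, start, end, strand))
    reads.sort(key=lambda t: (t.chrom, t.start, t.end, t.strand))
    return reads


# ---------------------------------------------------------------------------
# Planted-truth sidecar


def write_truth_sidecar(
    path: str | Path,
    *,
    genome: SyntheticGenomeSpec,
    arch: EnrichmentArchitecture,
    expr: ExpressionSpec | None = None,
    extra: Mapping[str, object] | None = None,
) -> None:
    """Record every planted parameter as JSON so tests can assert against truth."""
    doc: dict[str, object] = {
        "genome": dataclasses.asdict(genome),
        "architecture": dataclasses.asdict(arch),
    }
    if expr is not None:
        doc["expression"] = dataclasses.asdict(expr)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
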