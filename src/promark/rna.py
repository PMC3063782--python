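"""RNA-seq quantification: exon-overlap counting, RPKM, and induction ranking.

Reads are assigned to a gene when their interval overlaps the gene's exon
union; reads overlapping exons of more than one gene are discarded as
ambiguous and tallied separately, as are reads hitting no exon, so that
per-gene counts plus discards conserve the input. Expression is normalized
as RPKM (reads per kilobase of exon model per million mapped reads), fold
induction is the treated/control RPKM ratio with a pseudo floor in the
denominator, and genes are ranked by fold after an expressed-gene RPKM
filter on the treated condition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .genes import GeneModel
from .tags import Tag


@dataclass
class GeneCounts:
    """Per-gene read counts plus conservation bookkeeping."""

    counts: dict[str, int]
    n_ambiguous: int  # overlapped exons of more than one gene
    n_unassigned: int  # overlapped no exon

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.n_assigned + self.n_ambiguous + self.n_unassigned


@dataclass
class InductionRecord:
    """One gene's expression fold induction and rank among induced genes."""

    gene: str
    rpkm_control: float
    rpkm_treated: float
    fold_induction: float
    induced: bool
    rank: int


def count_reads_per_gene(
    alignments: Sequence[Tag], genes: Sequence[GeneModel]
) -> GeneCounts:
    """Assign each read to the single gene whose exon union it overlaps."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, g.name)
    counts = {g.name: 0 for g in genes}
    n_ambiguous = n_unassigned = 0
    for read in alignments:
        tree = trees.get(read.chrom)
        hits = {iv.data for iv in tree.overlap(read.start, read.end)} if tree else set()
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif len(hits) > 1:
            n_ambiguous += 1
        else:
            n_unassigned += 1
    return GeneCounts(counts, n_ambiguous, n_unassigned)


def rpkm(count: int, exon_model_length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_model_length_bp <= 0:
        raise ValueError("exon model length must be > 0")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be > 0")
    return count / (exon_model_length_bp / 1000.0) / (total_mapped_reads / 1e6)


def rpkm_table(
    counts: Mapping[str, int],
    genes: Sequence[GeneModel],
    total_mapped_reads: int | None = None,
) -> dict[str, float]:
    """RPKM for every gene; by default normalized by the summed gene counts."""
    if total_mapped_reads is None:
        total_mapped_reads = sum(counts.values())
    return {
        g.name: rpkm(counts.get(g.name, 0), g.exon_model_length, total_mapped_reads)
        for g in genes
    }


def one_read_rpkm(exon_model_length_bp: int, total_mapped_reads: int) -> float:
    """The RPKM contributed by a single read — the zero-control pseudo floor."""
    return rpkm(1, exon_model_length_bp, total_mapped_reads)


def percent(numerator: float, denominator: float) -> int:
    """Percentage rounded half-up to the nearest integer."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    import math

    return int(math.floor(100.0 * numerator / denominator + 0.5))


def expressed_fractions(
    counts_control: Mapping[str, int],
    counts_treated: Mapping[str, int],
    universe_size: int,
    *,
    rpkm_treated: Mapping[str, float] | None = None,
    rpkm_floor: float = 1.5,
) -> dict[str, int]:
    """Expressed-gene percentages over a fixed gene universe.

    Returns the percentage of the universe detected (>= 1 read) in each
    condition and in both, and — when treated RPKMs are supplied — the
    percentage of both-detected genes passing the RPKM floor, each rounded
    half-up to the nearest integer.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be > 0")
    det_c = {g for g, n in counts_control.items() if n >= 1}
    det_t = {g for g, n in counts_treated.items() if n >= 1}
    both = det_c & det_t
    out = {
        "pct_detected_control": percent(len(det_c), universe_size),
        "pct_detected_treated": percent(len(det_t), universe_size),
        "pct_detected_both": percent(len(both), universe_size),
        "n_detected_control": len(det_c),
        "n_detected_treated": len(det_t),
        "n_detected_both": len(both),
    }
    if rpkm_treated is not None:
        passing = {g for g in both if rpkm_treated.get(g, 0.0) > rpkm_floor}
        out["n_rpkm_passing"] = len(passing)
        out["pct_rpkm_passing_of_both"] = (
            percent(len(passing), len(both)) if both else 0
        )
    return out


def rank_induced(
    rpkm_control: Mapping[str, float],
    rpkm_treated: Mapping[str, float],
    *,
    rpkm_floor: float = 1.5,
    induced_cutoff: float = 2.0,
    n_top: int = 50,
    pseudo: Mapping[str, float] | float = 0.0,
) -> list[InductionRecord]:
    """Rank genes by expression fold induction under an RPKM filter.

    Genes with treated RPKM above ``rpkm_floor`` are retained; fold is
    treated / (control + pseudo), where ``pseudo`` is typically the one-read
    RPKM of the control library (keeping zero-control folds finite). Sorted
    descending by fold, ties broken by gene name; the top ``n_top`` records
    are returned with 1-based ranks, each flagged induced when its fold
    reaches ``induced_cutoff``.
    """
    records: list[tuple[float, str]] = []
    for gene, rt in rpkm_treated.items():
        if rt <= rpkm_floor:
            continue
        rc = rpkm_control.get(gene, 0.0)
        p = pseudo.get(gene, 0.0) if isinstance(pseudo, Mapping) else pseudo
        denom = rc + p
        fold = rt / denom if denom > 0 else float("inf")
        records.append((fold, gene))
    records.sort(key=lambda x: (-x[0], x[1]))
    out = []
    for rank, (fold, gene) in enumerate(records[:n_top], start=1):
        out.append(
            InductionRecord(
                gene=gene,
                rpkm_control=rpkm_control.get(gene, 0.0),
                rpkm_treated=rpkm_treated[gene],
                fold_induction=fold,
                induced=fold >= induced_cutoff,
                rank=rank,
            )
        )
    return out


def write_expression_table(
    records: Sequence[InductionRecord],
    counts_control: Mapping[str, int],
    counts_treated: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "gene",
                "raw_control",
                "raw_treated",
                "rpkm_control",
                "rpkm_treated",
                "fold_induction",
                "induced",
                "rank",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.gene,
                    counts_control.get(r.gene, 0),
                    counts_treated.get(r.gene, 0),
                    f"{r.rpkm_control:.4f}",
                    f"{r.rpkm_treated:.4f}",
                    f"{r.fold_induction:.4f}",
                    int(r.induced),
                    r.rank,
                ]
            )
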