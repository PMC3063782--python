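"""Gene models: named transcripts with strand, TSS and exon structure.

A gene model is the unit of annotation for every downstream stage: RNA-seq
reads are counted against its exon union, peaks are assigned to it through a
window around its transcription start site (TSS), and metagene profiles are
anchored at the TSS and oriented along its direction of transcription.

Coordinates are 0-based half-open throughout. On the ``+`` strand the TSS is
the transcript start; on the ``-`` strand it is the last base of the
transcript (``tx_end - 1``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GeneModel:
    """A named gene with strand, transcript extent and exon structure.

    Parameters
    ----------
    name
        Gene symbol; unique within an annotation set.
    chrom
        Chromosome name.
    strand
        ``'+'`` or ``'-'``.
    tx_start, tx_end
        Transcript extent, 0-based half-open.
    exons
        Non-overlapping, sorted ``(start, end)`` intervals inside the
        transcript. Every gene has at least one exon.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(f"invalid transcript extent [{self.tx_start}, {self.tx_end})")
        if not self.exons:
            raise ValueError(f"gene {self.name} has no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"gene {self.name}: empty exon ({start}, {end})")
            if start < self.tx_start or end > self.tx_end:
                raise ValueError(f"gene {self.name}: exon outside transcript")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"gene {self.name}: exons overlap or are unsorted")
            prev_end = end

    @property
    def tss(self) -> int:
        """Transcription start site (base coordinate, strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def exon_model_length(self) -> int:
        """Total exonic base pairs (the RPKM length denominator)."""
        return sum(end - start for start, end in self.exons)


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a refFlat-style tab-separated table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds"])
        for g in genes:
            w.writerow(
                [
                    g.name,
                    g.chrom,
                    g.strand,
                    g.tx_start,
                    g.tx_end,
                    ",".join(str(s) for s, _ in g.exons) + ",",
                    ",".join(str(e) for _, e in g.exons) + ",",
                ]
            )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read gene models from a refFlat-style tab-separated table."""
    genes: list[GeneModel] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header and header[0] != "name":  # headerless refFlat variant
            fh.seek(0)
            reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row:
                continue
            name, chrom, strand, tx_start, tx_end, starts, ends = row[:7]
            exon_starts = [int(x) for x in starts.rstrip(",").split(",")]
            exon_ends = [int(x) for x in ends.rstrip(",").split(",")]
            genes.append(
                GeneModel(
                    name=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(tx_start),
                    tx_end=int(tx_end),
                    exons=tuple(zip(exon_starts, exon_ends)),
                )
            )
    return genes


def genes_by_name(genes: Sequence[GeneModel]) -> dict[str, GeneModel]:
    return {g.name: g for g in genes}
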