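"""Aligned sequencing tags: I/O, filtering, and depth normalization.

A *tag* is one aligned short read reduced to a genomic interval plus strand
and a uniqueness flag. Libraries are prepared for peak calling in two steps
mirroring standard short-read bookkeeping:

1. ``filter_tags`` — drop reads that aligned equally well to multiple
   genomic positions, then collapse duplicated reads (same chromosome,
   5' position and strand) to a single tag, to limit PCR amplification bias.
2. ``subsample_to_match`` — seeded random sub-selection of the larger of two
   libraries so that treatment and control enter the peak caller at equal
   depth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Tag:
    """One aligned read as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str
    unique: bool = True

    @property
    def five_prime(self) -> int:
        """The 5' base of the read (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class LibraryStats:
    """Read bookkeeping through the filtering cascade.

    ``total`` input records, of which ``aligned`` are well-formed intervals,
    ``filtered`` additionally map uniquely, and ``used`` remain after
    duplicate collapse. Invariant: total >= aligned >= filtered >= used >= 0.
    """

    total: int = 0
    aligned: int = 0
    filtered: int = 0
    used: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "aligned": self.aligned,
            "filtered": self.filtered,
            "used": self.used,
        }


def sort_tags(tags: Iterable[Tag]) -> list[Tag]:
    return sorted(tags, key=lambda t: (t.chrom, t.start, t.end, t.strand))


def filter_tags(records: Sequence[Tag]) -> tuple[list[Tag], LibraryStats]:
    """Remove multi-mappers and collapse duplicate reads.

    Malformed intervals (start >= end) are rejected record-by-record; reads
    flagged non-unique are removed; duplicates — identical (chrom, 5' position,
    strand) — are collapsed to a single representative. Returns the retained
    tags in coordinate order together with the stage-by-stage counts.
    """
    stats = LibraryStats(total=len(records))
    well_formed = [t for t in records if t.start < t.end]
    stats.aligned = len(well_formed)
    unique = [t for t in well_formed if t.unique]
    stats.filtered = len(unique)
    seen: set[tuple[str, int, str]] = set()
    kept: list[Tag] = []
    for t in unique:
        key = (t.chrom, t.five_prime, t.strand)
        if key not in seen:
            seen.add(key)
            kept.append(t)
    stats.used = len(kept)
    return sort_tags(kept), stats


def subsample_to_match(
    a: Sequence[Tag], b: Sequence[Tag], seed: int
) -> tuple[list[Tag], list[Tag]]:
    """Down-sample the larger library, without replacement, to the smaller's size.

    The smaller library passes through unchanged; selection within the larger
    one is uniform and deterministic for a fixed seed. Relative tag order is
    preserved.
    """
    rng = np.random.default_rng(seed)

    def pick(tags: Sequence[Tag], n: int) -> list[Tag]:
        idx = np.sort(rng.choice(len(tags), size=n, replace=False))
        return [tags[i] for i in idx]

    if len(a) == len(b):
        return list(a), list(b)
    if len(a) > len(b):
        return pick(a, len(b)), list(b)
    return list(a), pick(b, len(a))


# ---------------------------------------------------------------------------
# I/O: BED6 and minimal SAM


def write_bed6(tags: Iterable[Tag], path: str | Path) -> None:
    """Write tags as BED6; the score column carries the uniqueness flag (1/0)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, t in enumerate(tags):
            w.writerow([t.chrom, t.start, t.end, f"tag{i}", 1 if t.unique else 0, t.strand])


def read_bed6(path: str | Path) -> list[Tag]:
    """Read tags from BED6; score != 0 marks a uniquely-mapped read."""
    tags: list[Tag] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith(("#", "track", "browser")):
                continue
            chrom, start, end = row[0], int(row[1]), int(row[2])
            score = float(row[4]) if len(row) > 4 and row[4] not in (".", "") else 1.0
            strand = row[5] if len(row) > 5 else "+"
            tags.append(Tag(chrom, start, end, strand, unique=score != 0))
    return tags


def read_sam(path: str | Path) -> list[Tag]:
    """Read tags from a (headered) SAM file via pysam.

    Unmapped and secondary records are dropped; mapping quality 0 marks a
    multi-mapper (``unique=False``), the ELAND-era convention for reads with
    several equally good placements.
    """
    import pysam

    tags: list[Tag] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            tags.append(
                Tag(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end or rec.reference_start + rec.query_length,
                    strand="-" if rec.is_reverse else "+",
                    unique=rec.mapping_quality > 0,
                )
            )
    return tags


def write_library_stats(stats: dict[str, LibraryStats], path: str | Path) -> None:
    """Write per-library filtering counts as a TSV (one row per stage)."""
    names = list(stats)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["stage"] + names)
        for stage in ("total", "aligned", "filtered", "used"):
            w.writerow([stage] + [getattr(stats[n], stage) for n in names])
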