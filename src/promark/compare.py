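"""Cross-condition peak matching, fold changes, and TSS annotation.

Peak lists from two conditions are matched by genomic overlap: peaks sharing
at least one base pair are chained transitively into a single union region,
and unmatched peaks become single-sided regions. The number of output regions
is the "combined" peak count. Fold changes are re-tallied from the underlying
(depth-matched) tag libraries over each union region — not taken from peak
scores — so that regions qualified in only one condition still receive a
finite fold. Regions are then annotated to every gene whose TSS ± span window
they overlap, and a per-gene summary keeps the highest fold change.
"""

from __future__ import annotations

import csv
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .genes import GeneModel
from .peaks import Peak
from .tags import Tag


@dataclass
class MatchedRegion:
    """Union region pairing treatment/control peak evidence across conditions."""

    chrom: str
    start: int
    end: int
    treated_peaks: tuple[Peak, ...] = ()
    control_peaks: tuple[Peak, ...] = ()
    treat_tags: int | None = None
    control_tags: int | None = None
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if not self.treated_peaks and not self.control_peaks:
            raise ValueError("a matched region needs at least one contributing peak")


@dataclass
class TssAnnotation:
    """A matched region assigned to a gene through its TSS ± span window."""

    gene: str
    region: MatchedRegion
    distance_to_tss: int  # signed, positive downstream of transcription
    within_span: bool = True


def match_peaks(treated: Sequence[Peak], control: Sequence[Peak]) -> list[MatchedRegion]:
    """Chain overlapping peaks (>= 1 bp) across conditions into union regions.

    Overlap is transitive: a control peak bridging two treated peaks merges
    all three into one region. Output regions are pairwise disjoint, sorted,
    and their union equals the union of all input peaks.
    """
    labeled = [(p, "T") for p in treated] + [(p, "C") for p in control]
    labeled.sort(key=lambda x: (x[0].chrom, x[0].start, x[0].end))
    regions: list[MatchedRegion] = []
    cur: list[tuple[Peak, str]] = []
    cur_chrom, cur_end = None, -1
    for p, side in labeled:
        if cur and p.chrom == cur_chrom and p.start < cur_end:
            cur.append((p, side))
            cur_end = max(cur_end, p.end)
        else:
            if cur:
                regions.append(_flush(cur_chrom, cur, cur_end))
            cur = [(p, side)]
            cur_chrom, cur_end = p.chrom, p.end
    if cur:
        regions.append(_flush(cur_chrom, cur, cur_end))
    return regions


def _flush(chrom: str, members: list[tuple[Peak, str]], end: int) -> MatchedRegion:
    return MatchedRegion(
        chrom=chrom,
        start=min(p.start for p, _ in members),
        end=end,
        treated_peaks=tuple(p for p, s in members if s == "T"),
        control_peaks=tuple(p for p, s in members if s == "C"),
    )


class _TagIndex:
    """5'-position index per chromosome for O(log n) region tallies."""

    def __init__(self, tags: Iterable[Tag]):
        self._pos: dict[str, list[int]] = {}
        for t in tags:
            self._pos.setdefault(t.chrom, []).append(t.five_prime)
        for v in self._pos.values():
            v.sort()

    def count(self, chrom: str, start: int, end: int) -> int:
        pos = self._pos.get(chrom, [])
        return bisect_left(pos, end) - bisect_left(pos, start)


def region_fold_change(
    region: MatchedRegion,
    treat_tags: Sequence[Tag] | _TagIndex,
    control_tags: Sequence[Tag] | _TagIndex,
    *,
    pseudocount: float = 1.0,
) -> float:
    """Treated/control tag-count ratio over the union region.

    Counts are tallied from the tag libraries by 5' position within
    [start, end); the pseudocount keeps single-sided regions finite:
    fold = (treat + pseudo) / (control + pseudo).
    """
    ti = treat_tags if isinstance(treat_tags, _TagIndex) else _TagIndex(treat_tags)
    ci = control_tags if isinstance(control_tags, _TagIndex) else _TagIndex(control_tags)
    t = ti.count(region.chrom, region.start, region.end)
    c = ci.count(region.chrom, region.start, region.end)
    return (t + pseudocount) / (c + pseudocount)


def add_fold_changes(
    regions: Sequence[MatchedRegion],
    treat_tags: Sequence[Tag],
    control_tags: Sequence[Tag],
    *,
    pseudocount: float = 1.0,
) -> list[MatchedRegion]:
    """Fill treat/control tallies and fold change on every region (in place)."""
    ti = _TagIndex(treat_tags)
    ci = _TagIndex(control_tags)
    for r in regions:
        r.treat_tags = ti.count(r.chrom, r.start, r.end)
        r.control_tags = ci.count(r.chrom, r.start, r.end)
        r.fold_change = (r.treat_tags + pseudocount) / (r.control_tags + pseudocount)
    return list(regions)


def annotate_tss(
    regions: Sequence[MatchedRegion],
    genes: Sequence[GeneModel],
    span: int = 5000,
) -> list[TssAnnotation]:
    """Annotate each region to every gene whose TSS ± span window it overlaps.

    The distance is measured from the TSS to the nearest region edge (0 if
    the region covers the TSS), signed positive in the direction of
    transcription.
    """
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)
    out: list[TssAnnotation] = []
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        lo, hi = g.tss - span, g.tss + span
        hits = sorted(tree.overlap(max(lo, 0), hi), key=lambda iv: iv.begin)
        for iv in hits:
            region = regions[iv.data]
            if region.start <= g.tss < region.end:
                d_gen = 0
            elif region.start > g.tss:
                d_gen = region.start - g.tss
            else:
                d_gen = (region.end - 1) - g.tss  # negative: region upstream
            dist = d_gen if g.strand == "+" else -d_gen
            out.append(TssAnnotation(gene=g.name, region=region, distance_to_tss=dist))
    return out


def best_fold_per_gene(annotations: Sequence[TssAnnotation]) -> dict[str, float]:
    """Per gene, the maximum fold change among its within-span regions.

    Genes without any within-span region are absent from the map. Regions
    must have fold changes filled in (``add_fold_changes``).
    """
    best: dict[str, float] = {}
    for a in annotations:
        if not a.within_span:
            continue
        if a.region.fold_change is None:
            raise ValueError("region fold changes must be computed before ranking")
        f = a.region.fold_change
        if a.gene not in best or f > best[a.gene]:
            best[a.gene] = f
    return best


# ---------------------------------------------------------------------------
# I/O


def write_matched_regions(regions: Iterable[MatchedRegion], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "chrom",
                "start",
                "end",
                "n_treated_peaks",
                "n_control_peaks",
                "treat_tags",
                "control_tags",
                "fold_change",
            ]
        )
        for r in regions:
            w.writerow(
                [
                    r.chrom,
                    r.start,
                    r.end,
                    len(r.treated_peaks),
                    len(r.control_peaks),
                    r.treat_tags if r.treat_tags is not None else "",
                    r.control_tags if r.control_tags is not None else "",
                    f"{r.fold_change:.4f}" if r.fold_change is not None else "",
                ]
            )
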