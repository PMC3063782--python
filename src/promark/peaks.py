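"""Window-consolidation peak calling with sample-swap empirical FDR.

The genome is tiled into fixed-width consolidating windows (default 100 bp).
Each tag is assigned to the window containing its 5' position. Per window, a
one-sided Poisson tail test compares the treatment count against a rate taken
from the depth-scaled input count, floored at the global input mean per
window. Significant windows lying within one window-width of each other are
consolidated into candidate regions, and a candidate qualifies as a peak only
if it passes all of: a region-level Poisson p-value below ``p_threshold``, a
region-level log2 enrichment ratio (with pseudocount 1 on both sides) of at
least ``min_log2_ratio``, and at least ``min_tags`` treatment tags.

The reported p-values are raw (no multiple-testing correction); the raw
p<0.05 gate acts jointly with the ratio and tag-count gates, and the overall
error rate is quantified empirically by ``estimate_fdr``, which swaps the
treatment and input libraries and reports the ratio of swapped to forward
peak counts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .tags import Tag


@dataclass
class PeakParams:
    """Qualification thresholds for the window-consolidation caller."""

    window: int = 100
    p_threshold: float = 0.05
    min_log2_ratio: float = 1.0
    min_tags: int = 40
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_tags < 0:
            raise ValueError("min_tags must be >= 0")


@dataclass
class Peak:
    """A qualified enriched region (window-aligned, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    treat_tags: int
    control_tags: float  # depth-scaled input tally over the region
    log2_ratio: float
    p_value: float


@dataclass
class FdrEstimate:
    """Empirical FDR from a treatment/input sample swap."""

    forward_peaks: int
    swapped_peaks: int

    @property
    def fdr(self) -> float | None:
        """swapped/forward peak-count ratio; None when no forward peaks exist."""
        if self.forward_peaks == 0:
            return None
        return self.swapped_peaks / self.forward_peaks


@dataclass
class WindowCounts:
    """Per-chromosome window tag counts plus out-of-bounds bookkeeping."""

    counts: dict[str, np.ndarray]
    window: int
    n_assigned: int
    n_rejected: int

    @property
    def total_windows(self) -> int:
        return sum(len(v) for v in self.counts.values())


def count_window_tags(
    tags: Iterable[Tag], chrom_sizes: Mapping[str, int], window: int
) -> WindowCounts:
    """Count tags per consolidating window by 5' position (strand-aware).

    Tags whose 5' position falls outside the declared chromosome bounds (or
    on an undeclared chromosome) are rejected and counted.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    counts = {
        c: np.zeros((size + window - 1) // window, dtype=np.int64)
        for c, size in chrom_sizes.items()
    }
    n_assigned = n_rejected = 0
    for t in tags:
        arr = counts.get(t.chrom)
        pos = t.five_prime
        if arr is None or not 0 <= pos < chrom_sizes[t.chrom]:
            n_rejected += 1
            continue
        arr[pos // window] += 1
        n_assigned += 1
    return WindowCounts(counts, window, n_assigned, n_rejected)


def call_peaks(
    treat_tags: Sequence[Tag],
    input_tags: Sequence[Tag],
    chrom_sizes: Mapping[str, int],
    params: PeakParams | None = None,
    *,
    scale: float | None = None,
) -> list[Peak]:
    """Call qualified peaks from treatment vs input tag libraries.

    ``scale`` multiplies input window counts to the treatment depth; by
    default it is ``len(treat)/len(input)`` (1.0 for libraries already
    depth-matched by random sub-selection). Returns peaks sorted by position.
    """
    params = params or PeakParams()
    if not chrom_sizes or all(v <= 0 for v in chrom_sizes.values()):
        raise ValueError("genome has zero size")
    if len(treat_tags) == 0:
        return []
    if scale is None:
        scale = len(treat_tags) / len(input_tags) if len(input_tags) else 1.0

    wc_t = count_window_tags(treat_tags, chrom_sizes, params.window)
    wc_c = count_window_tags(input_tags, chrom_sizes, params.window)
    total_windows = wc_t.total_windows
    floor = scale * wc_c.n_assigned / total_windows if total_windows else 0.0
    floor = max(floor, 1e-9)

    peaks: list[Peak] = []
    for chrom in chrom_sizes:
        t = wc_t.counts[chrom]
        c = wc_c.counts[chrom].astype(float) * scale
        lam = np.maximum(c, floor)
        with np.errstate(divide="ignore"):
            pvals = stats.poisson.sf(t - 1, lam)
        sig = np.flatnonzero((pvals < params.p_threshold) & (t > 0))
        for i0, i1 in _consolidate(sig):
            start = i0 * params.window
            end = min((i1 + 1) * params.window, chrom_sizes[chrom])
            treat_n = int(t[i0 : i1 + 1].sum())
            ctrl_n = float(c[i0 : i1 + 1].sum())
            lam_r = max(ctrl_n, floor * (i1 - i0 + 1))
            p_r = float(stats.poisson.sf(treat_n - 1, lam_r))
            ratio = math.log2(
                (treat_n + params.pseudocount) / (ctrl_n + params.pseudocount)
            )
            if (
                treat_n >= params.min_tags
                and ratio >= params.min_log2_ratio
                and p_r < params.p_threshold
            ):
                peaks.append(Peak(chrom, start, end, treat_n, ctrl_n, ratio, p_r))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def _consolidate(sig_indices: np.ndarray) -> list[tuple[int, int]]:
    """Merge significant window indices separated by at most one window-width.

    Indices ``i`` and ``j`` (i<j) join one candidate region iff ``j-i <= 2``,
    i.e. at most one non-significant window (one window-width of gap) lies
    between them.
    """
    runs: list[tuple[int, int]] = []
    for idx in sig_indices:
        idx = int(idx)
        if runs and idx - runs[-1][1] <= 2:
            runs[-1] = (runs[-1][0], idx)
        else:
            runs.append((idx, idx))
    return runs


def estimate_fdr(
    treat_tags: Sequence[Tag],
    input_tags: Sequence[Tag],
    chrom_sizes: Mapping[str, int],
    params: PeakParams | None = None,
) -> FdrEstimate:
    """Empirical FDR: re-call peaks with the libraries swapped.

    Peaks found with input playing the role of treatment are, by
    construction, false discoveries; their count over the forward peak count
    estimates the overall FDR of the forward call.
    """
    forward = call_peaks(treat_tags, input_tags, chrom_sizes, params)
    swapped = call_peaks(input_tags, treat_tags, chrom_sizes, params)
    return FdrEstimate(forward_peaks=len(forward), swapped_peaks=len(swapped))


# ---------------------------------------------------------------------------
# I/O


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """BED6+4: name, score=round(10*log2ratio), strand '.', then the stats columns."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, p in enumerate(peaks):
            w.writerow(
                [
                    p.chrom,
                    p.start,
                    p.end,
                    f"peak{i}",
                    int(round(10 * p.log2_ratio)),
                    ".",
                    p.treat_tags,
                    f"{p.control_tags:.3f}",
                    f"{p.log2_ratio:.4f}",
                    f"{p.p_value:.3e}",
                ]
            )


def read_peaks_bed(path: str | Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            peaks.append(
                Peak(
                    chrom=row[0],
                    start=int(row[1]),
                    end=int(row[2]),
                    treat_tags=int(row[6]),
                    control_tags=float(row[7]),
                    log2_ratio=float(row[8]),
                    p_value=float(row[9]),
                )
            )
    return peaks


def write_window_bedgraph(wc: WindowCounts, path: str | Path) -> None:
    """Genome-wide per-window tag counts as bedGraph (zero windows omitted)."""
    with open(path, "w", newline="") as fh:
        for chrom in wc.counts:
            arr = wc.counts[chrom]
            for i in np.flatnonzero(arr):
                fh.write(f"{chrom}\t{i * wc.window}\t{(i + 1) * wc.window}\t{arr[i]}\n")
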