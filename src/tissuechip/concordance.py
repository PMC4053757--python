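"""Replicate reproducibility statistics.

Two complementary views of agreement between biological replicates:

* the window-correlation procedure — pool the replicates' peak calls,
  tile the peaks into non-overlapping fixed-width (default 100 nt)
  windows, count each replicate's read 5' ends per window, and take the
  Pearson correlation of the two count vectors; and
* directional peak-set overlap — the fraction of one replicate's peaks
  overlapping at least one peak of the other.

Both are reported side by side because published "reproducibility"
percentages for this kind of data do not pin down which was meant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .model import GenomicInterval, IntervalIndex, PeakSet, merge_intervals

__all__ = [
    "ReadTrack",
    "WindowCounts",
    "tile_windows",
    "count_reads",
    "pearson",
    "replicate_correlation",
    "overlap_fraction",
    "concordance_summary",
]


@dataclass
class ReadTrack:
    """Sequenced reads reduced to their 5' positions."""

    label: str
    reads: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in self.reads:
            if pos < 0:
                raise ValueError(f"read position must be >= 0, got {pos}")
            by_chrom.setdefault(chrom, []).append(pos)
        self._positions = {
            chrom: np.sort(np.asarray(pos, dtype=np.int64))
            for chrom, pos in by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.reads)

    def positions(self, chrom: str) -> np.ndarray:
        return self._positions.get(chrom, np.empty(0, dtype=np.int64))

    def iter_reads(self) -> Iterator[tuple[str, int]]:
        return iter(self.reads)


@dataclass
class WindowCounts:
    """Per-window read counts for one or more samples."""

    windows: list[GenomicInterval]
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for label, c in self.counts.items():
            if len(c) != len(self.windows):
                raise ValueError(f"counts for {label!r} do not match windows")
            if (np.asarray(c) < 0).any():
                raise ValueError("negative counts")


def tile_windows(
    peaks: PeakSet | Iterable[GenomicInterval], width: int
) -> list[GenomicInterval]:
    """Tile merged peak regions into non-overlapping width-bp windows.

    Tiling starts at each merged peak's start; a final partial window is
    retained so the windows cover exactly the peak bases.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    intervals = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    merged = merge_intervals(intervals)
    windows: list[GenomicInterval] = []
    for iv in merged:
        for s in range(iv.start, iv.end, width):
            windows.append(GenomicInterval(iv.chrom, s, min(s + width, iv.end)))
    return windows


def count_reads(track: ReadTrack, windows: Sequence[GenomicInterval]) -> np.ndarray:
    """Count reads whose 5' position falls in each (disjoint) window.

    Half-open membership: a read at a window's end coordinate belongs to
    the next window, if any. Reads outside every window are ignored.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        pos = track.positions(chrom)
        if len(pos) == 0:
            continue
        starts = np.array([windows[i].start for i in idxs], dtype=np.int64)
        ends = np.array([windows[i].end for i in idxs], dtype=np.int64)
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        which = np.searchsorted(starts, pos, side="right") - 1
        ok = which >= 0
        ok[ok] &= pos[ok] < ends[which[ok]]
        hit = np.bincount(which[ok], minlength=len(starts))
        for j, n in zip(order, hit):
            counts[idxs[j]] += int(n)
    return counts


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def replicate_correlation(
    pooled_peaks: PeakSet | Iterable[GenomicInterval],
    track_a: ReadTrack,
    track_b: ReadTrack,
    width: int = 100,
) -> float:
    """Window-correlation reproducibility between two replicates.

    Peaks called from pooled reads are tiled into non-overlapping
    ``width``-nt windows; raw reads per window are counted from each
    replicate, and the Pearson correlation of the counts is returned.
    """
    windows = tile_windows(pooled_peaks, width)
    if len(windows) < 2:
        raise ValueError(f"need >= 2 windows, got {len(windows)}")
    ca = count_reads(track_a, windows)
    cb = count_reads(track_b, windows)
    return pearson(ca, cb)


def overlap_fraction(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> float:
    """Directional fraction of A's peaks overlapping at least one B peak."""
    a_merged = a.merged()
    if len(a_merged) == 0:
        raise ValueError("overlap fraction undefined for an empty peak set")
    index = IntervalIndex(b.intervals)
    hits = sum(
        1 for iv in a_merged.intervals if index.overlaps(iv, min_overlap)
    )
    return hits / len(a_merged)


def concordance_summary(
    pooled_peaks: PeakSet,
    track_a: ReadTrack,
    track_b: ReadTrack,
    peaks_a: PeakSet | None = None,
    peaks_b: PeakSet | None = None,
    width: int = 100,
    min_overlap: int = 1,
) -> dict:
    """JSON-ready replicate summary: window r plus directional overlaps."""
    windows = tile_windows(pooled_peaks, width)
    out: dict = {"n_windows": len(windows), "window_width": width}
    if len(windows) >= 2:
        ca = count_reads(track_a, windows)
        cb = count_reads(track_b, windows)
        out["r"] = pearson(ca, cb)
    else:
        out["r"] = None
    if peaks_a is not None and peaks_b is not None:
        out["fraction_A_in_B"] = overlap_fraction(peaks_a, peaks_b, min_overlap)
        out["fraction_B_in_A"] = overlap_fraction(peaks_b, peaks_a, min_overlap)
    return out
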