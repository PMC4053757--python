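"""Core genomic data types and interval arithmetic.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` bases. GFF3 input (1-based, closed)
is converted on read. Two intervals that merely touch (``a.end == b.start``)
share zero bases: they are neither merged nor counted as overlapping, which
keeps adjacency and overlap arithmetic exact and consistent with a minimum
overlap of one base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "GenomeAnnotation",
    "PipelineParams",
    "IntervalIndex",
    "merge_intervals",
    "overlap_bp",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes).

    Touching half-open intervals share zero bases.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge strictly overlapping intervals into a sorted disjoint list.

    Touching intervals (zero shared bases) are kept separate. The union of
    covered bases is preserved exactly.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


@dataclass(frozen=True)
class Peak:
    """A scored binding-site call (one narrowPeak / BED record).

    ``qvalue`` is the peak caller's q as a probability in (0, 1];
    narrowPeak stores -log10(q), converted on read. ``summit`` is the
    point-source offset from ``interval.start`` (narrowPeak column 10),
    or None. ``extra`` holds any trailing columns opaquely so that
    read -> write round trips preserve them.
    """

    interval: GenomicInterval
    name: str = "."
    score: float | None = None
    strand: str = "."
    signal: float | None = None
    pvalue: float | None = None  # -log10 p, narrowPeak convention
    qvalue: float | None = None  # plain probability
    summit: int | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.qvalue is not None and not (0.0 < self.qvalue <= 1.0):
            raise ValueError(f"qvalue must be in (0, 1], got {self.qvalue}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass
class PeakSet:
    """All peaks for one (factor, tissue) ChIP dataset.

    Peaks are kept sorted by (chrom, start, end). ``key`` is the
    "factor@tissue" dataset identifier used throughout classification.
    """

    factor: str
    tissue: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks,
            key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end),
        )

    @property
    def key(self) -> str:
        return f"{self.factor}@{self.tissue}"

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def merged(self) -> "PeakSet":
        """Merge-normalized copy: no two peaks on a chromosome overlap.

        Merged peaks keep only coordinates (scores are not combinable).
        """
        merged = merge_intervals(self.intervals)
        return PeakSet(
            self.factor, self.tissue, [Peak(interval=iv) for iv in merged]
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-derived transcript start site.

    The TSS is ``span.start`` on the + strand and ``span.end - 1`` on the
    - strand (both 0-based genomic positions).
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )
        if self.chrom != self.span.chrom:
            raise ValueError(f"gene {self.gene_id}: chrom/span mismatch")

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1


class GenomeAnnotation:
    """Chromosome lengths plus a gene catalogue keyed by unique gene id."""

    def __init__(
        self,
        chromosomes: Mapping[str, int],
        genes: Iterable[GeneModel],
        x_chromosomes: Iterable[str] = (),
    ) -> None:
        self.chromosomes: dict[str, int] = dict(chromosomes)
        self.x_chromosomes: frozenset[str] = frozenset(x_chromosomes)
        for x in self.x_chromosomes:
            if x not in self.chromosomes:
                raise ValueError(f"X chromosome {x!r} not in chromosome table")
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            if g.chrom not in self.chromosomes:
                raise ValueError(
                    f"gene {g.gene_id}: unknown chromosome {g.chrom!r}"
                )
            if g.span.end > self.chromosomes[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id}: span ends at {g.span.end} beyond "
                    f"{g.chrom} length {self.chromosomes[g.chrom]}"
                )
            self.genes[g.gene_id] = g
        self._tss_cache: dict[str, tuple[np.ndarray, list[str]]] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def is_x(self, chrom: str) -> bool:
        return chrom in self.x_chromosomes

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def tss_index(self) -> dict[str, tuple[np.ndarray, list[str]]]:
        """Per-chromosome (sorted TSS positions, parallel gene ids)."""
        if self._tss_cache is None:
            by_chrom: dict[str, list[tuple[int, str]]] = {}
            for g in self.genes.values():
                by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
            cache = {}
            for chrom, pairs in by_chrom.items():
                pairs.sort()
                cache[chrom] = (
                    np.array([p[0] for p in pairs], dtype=np.int64),
                    [p[1] for p in pairs],
                )
            self._tss_cache = cache
        return self._tss_cache


@dataclass(frozen=True)
class PipelineParams:
    """All fixed thresholds of the analysis, with study defaults.

    q_threshold
        peak q-value cutoff (inclusive), default 0.001.
    high_dist / low_dist
        TSS distance tiers: < high_dist is a high-confidence target,
        [high_dist, low_dist] low confidence, > low_dist unassigned.
    window
        replicate-concordance window width in nucleotides.
    min_overlap
        bases two intervals must share to count as overlapping.
    germline_genome_fraction
        reference fraction of germline-expressed genes in the genome.
    term_min_fold / term_alpha / term_top
        term-enrichment report filters: fold > 2, P < 0.05, top 10.
    """

    q_threshold: float = 0.001
    high_dist: int = 500
    low_dist: int = 2000
    window: int = 100
    min_overlap: int = 1
    germline_genome_fraction: float = 0.105
    term_min_fold: float = 2.0
    term_alpha: float = 0.05
    term_top: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.q_threshold <= 1.0):
            raise ValueError("q_threshold must be in (0, 1]")
        if not (0 < self.high_dist < self.low_dist):
            raise ValueError("require 0 < high_dist < low_dist")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")

    def with_overrides(self, **kwargs) -> "PipelineParams":
        return replace(self, **kwargs)


class IntervalIndex:
    """Sorted-sweep overlap queries against a fixed set of intervals.

    The input is merge-normalized internally, so queries reduce to a
    binary search over disjoint sorted intervals per chromosome.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        merged = merge_intervals(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def overlaps(self, iv: GenomicInterval, min_overlap: int = 1) -> bool:
        """True iff some stored (merged) interval shares >= min_overlap
        bases with iv."""
        return self.max_overlap(iv) >= min_overlap

    def max_overlap(self, iv: GenomicInterval) -> int:
        """Largest per-interval overlap (bp) between iv and the stored set."""
        ends = self._ends.get(iv.chrom)
        if ends is None:
            return 0
        starts = self._starts[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            return 0
        ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
        return int(ov.max(initial=0))

    def covered_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in zip(self._starts.values(), self._ends.values()))
        )


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by a union of intervals."""
    return sum(iv.width for iv in merge_intervals(intervals))
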