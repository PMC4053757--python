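"""Per-category descriptive site properties.

Width statistics (mean +/- standard error), genomic context (promoter /
gene body / intergenic, decided by the site midpoint so that every site
gets exactly one label), and the fraction of sites not assignable to any
nearby gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classification import ClassifiedSites
from .model import GenomeAnnotation, GenomicInterval, IntervalIndex, Peak
from .targets import AssignmentTable

__all__ = [
    "WidthStats",
    "ContextCounts",
    "width_stats",
    "genomic_context",
    "context_labels",
    "unassignable_fraction",
]


@dataclass(frozen=True)
class WidthStats:
    """Mean binding-site width for one category, with its standard error.

    se is the sample standard deviation over sqrt(n); NaN when n < 2.
    """

    category: str
    n: int
    mean: float
    se: float


def width_stats(
    classified: ClassifiedSites | Mapping[str, Sequence[Peak]],
) -> list[WidthStats]:
    """Per-category mean and standard error of site widths."""
    sites = classified.sites if isinstance(classified, ClassifiedSites) else classified
    out = []
    for category, peaks in sites.items():
        widths = np.array([p.interval.width for p in peaks], dtype=float)
        n = len(widths)
        if n == 0:
            out.append(WidthStats(category, 0, math.nan, math.nan))
        elif n == 1:
            out.append(WidthStats(category, 1, float(widths[0]), math.nan))
        else:
            out.append(
                WidthStats(
                    category,
                    n,
                    float(widths.mean()),
                    float(widths.std(ddof=1) / math.sqrt(n)),
                )
            )
    return out


@dataclass(frozen=True)
class ContextCounts:
    """Counts of sites in promoter / gene body / intergenic context."""

    promoter: int
    gene_body: int
    intergenic: int
    promoter_bp: int
    category: str | None = None

    @property
    def total(self) -> int:
        return self.promoter + self.gene_body + self.intergenic


def _promoter_windows(
    annotation: GenomeAnnotation, promoter_bp: int
) -> list[GenomicInterval]:
    windows = []
    for g in annotation.genes.values():
        if g.strand == "+":
            start, end = g.tss - promoter_bp, g.tss
        else:
            start, end = g.tss + 1, g.tss + 1 + promoter_bp
        start = max(start, 0)
        if end > start:
            windows.append(GenomicInterval(g.chrom, start, end))
    return windows


def context_labels(
    sites: Iterable[GenomicInterval],
    annotation: GenomeAnnotation,
    promoter_bp: int = 500,
) -> list[str]:
    """Label each site by its midpoint: promoter beats gene body beats
    intergenic. Promoter windows extend promoter_bp upstream of each TSS,
    strand-aware."""
    if promoter_bp <= 0:
        raise ValueError("promoter_bp must be > 0")
    promoters = IntervalIndex(_promoter_windows(annotation, promoter_bp))
    bodies = IntervalIndex(g.span for g in annotation.genes.values())
    labels = []
    for site in sites:
        mid = site.midpoint
        point = GenomicInterval(site.chrom, mid, mid + 1)
        if promoters.overlaps(point):
            labels.append("promoter")
        elif bodies.overlaps(point):
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    return labels


def genomic_context(
    sites: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
    promoter_bp: int = 500,
    category: str | None = None,
) -> ContextCounts:
    labels = context_labels(sites, annotation, promoter_bp)
    return ContextCounts(
        promoter=labels.count("promoter"),
        gene_body=labels.count("gene_body"),
        intergenic=labels.count("intergenic"),
        promoter_bp=promoter_bp,
        category=category,
    )


def unassignable_fraction(table: AssignmentTable) -> float:
    """Fraction of sites with no candidate gene within the low tier."""
    if table.n_sites == 0:
        raise ValueError("fraction undefined for zero sites")
    return len(table.unassigned_sites) / table.n_sites


def plot_category_bars(values: Mapping[str, float], ylabel: str, path) -> None:
    """Optional bar chart of one per-category statistic (headless backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    names = list(values)
    ax.bar(range(len(names)), [values[n] for n in names], color="#4878cf")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
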