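"""Candidate target-gene assignment by TSS distance tiers.

A gene is a high-confidence candidate target of a binding site when its
transcript start site lies less than ``high_dist`` (default 500) bp from
the site, a low-confidence target between ``high_dist`` and ``low_dist``
(default 2,000) bp inclusive, and sites farther than ``low_dist`` from
every TSS are left unassigned. Distance is measured from the TSS to the
nearest base of the site (0 when the TSS falls inside the site), is
unstranded, and a site may be assigned to several genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .model import GenomeAnnotation, GeneModel, GenomicInterval, PipelineParams

__all__ = [
    "TargetAssignment",
    "AssignmentTable",
    "site_tss_distance",
    "assign_targets",
    "target_gene_set",
]

Tier = Literal["high", "low"]


@dataclass(frozen=True)
class TargetAssignment:
    """One (site, gene) link with its TSS distance and confidence tier."""

    site: GenomicInterval
    gene_id: str
    distance: int
    tier: Tier
    category: str | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.tier not in ("high", "low"):
            raise ValueError(f"tier must be 'high' or 'low', got {self.tier!r}")


@dataclass
class AssignmentTable:
    """All assignments for one site list, plus the unassignable sites."""

    assignments: list[TargetAssignment]
    unassigned_sites: list[GenomicInterval]
    n_sites: int

    @property
    def assigned_sites(self) -> list[GenomicInterval]:
        return list(dict.fromkeys(a.site for a in self.assignments))


def site_tss_distance(site: GenomicInterval, gene: GeneModel) -> float:
    """Distance (bp) from a gene's TSS to the nearest base of a site.

    0 when the TSS lies inside the site; infinity for a different
    chromosome.
    """
    if site.chrom != gene.chrom:
        return math.inf
    tss = gene.tss
    if tss < site.start:
        return site.start - tss
    if tss >= site.end:
        return tss - (site.end - 1)
    return 0


def assign_targets(
    sites: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
    params: PipelineParams | None = None,
    category: str | None = None,
) -> AssignmentTable:
    """Assign every site to all genes within the distance tiers.

    Every gene with TSS distance < high_dist yields a high-tier
    assignment and every gene within [high_dist, low_dist] a low-tier
    one; sites with no gene within low_dist go to ``unassigned_sites``.
    """
    if params is None:
        params = PipelineParams()
    if len(annotation) == 0:
        raise ValueError("annotation contains no genes")
    tss_index = annotation.tss_index()

    assignments: list[TargetAssignment] = []
    unassigned: list[GenomicInterval] = []
    for site in sites:
        entry = tss_index.get(site.chrom)
        found = False
        if entry is not None:
            positions, gene_ids = entry
            lo = int(np.searchsorted(positions, site.start - params.low_dist, side="left"))
            hi = int(np.searchsorted(positions, site.end - 1 + params.low_dist, side="right"))
            for j in range(lo, hi):
                tss = int(positions[j])
                if tss < site.start:
                    d = site.start - tss
                elif tss >= site.end:
                    d = tss - (site.end - 1)
                else:
                    d = 0
                if d > params.low_dist:
                    continue
                tier: Tier = "high" if d < params.high_dist else "low"
                assignments.append(
                    TargetAssignment(site, gene_ids[j], d, tier, category)
                )
                found = True
        if not found:
            unassigned.append(site)
    return AssignmentTable(assignments, unassigned, n_sites=len(sites))


def target_gene_set(
    table: AssignmentTable, tiers: Iterable[str] = ("high", "low")
) -> set[str]:
    """Unique candidate target genes across the selected confidence tiers."""
    wanted = set(tiers)
    return {a.gene_id for a in table.assignments if a.tier in wanted}
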