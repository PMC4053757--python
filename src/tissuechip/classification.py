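"""Partition binding sites into mutually exclusive tissue categories.

A category is a boolean recipe over named factor@tissue peak sets: an
*anchor* set supplies the candidate site intervals, *include* sets must
all overlap a site, and *exclude* sets must not. Candidates satisfying
more than one category's predicate are awarded to the earliest category
in the configured priority order and logged, which enforces mutual
exclusivity even when the recipes alone do not guarantee it.

The shipped defaults encode the four C. elegans DRM/heterochromatin
categories used to dissect LIN-35 (Rb), EFL-1 (E2F), DPL-1 (DP) and
HPL-2 (HP1-like) binding across germline, soma and intestine:

* germline-specific — bound by germline EFL-1 and germline DPL-1 but
  not somatic DPL-1 (germline LIN-35 is not required: it binds weakly);
* soma-specific — bound by somatic EFL-1, DPL-1 and LIN-35 but not
  germline EFL-1 or intestinal HPL-2 (the latter removes promiscuous
  "HOT" regions);
* intestine-specific — bound by intestinal LIN-35 and intestinal HPL-2
  but not somatic or intestinal EFL-1;
* broadly bound — bound by germline EFL-1, intestinal DPL-1 and somatic
  LIN-35, the strongest binder in each tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import GenomicInterval, IntervalIndex, Peak, PeakSet

__all__ = [
    "CategoryDefinition",
    "ClassifiedSites",
    "ConflictRecord",
    "site_support",
    "classify",
    "default_category_definitions",
    "DEFAULT_DATASET_KEYS",
]


@dataclass(frozen=True)
class CategoryDefinition:
    """Boolean include/exclude recipe for one tissue category."""

    name: str
    anchor: str
    include: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "include", tuple(self.include))
        object.__setattr__(self, "exclude", tuple(self.exclude))
        if self.anchor not in self.include:
            raise ValueError(
                f"category {self.name!r}: anchor {self.anchor!r} must be in include"
            )
        common = set(self.include) & set(self.exclude)
        if common:
            raise ValueError(
                f"category {self.name!r}: keys in both include and exclude: {sorted(common)}"
            )

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys((*self.include, *self.exclude)))


@dataclass(frozen=True)
class ConflictRecord:
    interval: GenomicInterval
    winner: str
    losers: tuple[str, ...]


@dataclass
class ClassifiedSites:
    """Disjoint per-category site lists plus the conflict log.

    ``sites`` maps category name to the anchor peaks assigned to it;
    ``unclassified`` maps each anchor dataset key to its peaks that
    satisfied no category; ``conflicts`` records candidates that matched
    more than one category and the priority winner.
    """

    sites: dict[str, list[Peak]]
    conflicts: list[ConflictRecord] = field(default_factory=list)
    unclassified: dict[str, list[Peak]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(peaks) for name, peaks in self.sites.items()}

    def intervals(self, category: str) -> list[GenomicInterval]:
        return [p.interval for p in self.sites[category]]


def site_support(
    site: GenomicInterval,
    peaksets: Mapping[str, PeakSet],
    min_overlap: int = 1,
    indexes: Mapping[str, IntervalIndex] | None = None,
) -> dict[str, bool]:
    """Which datasets bind a site (>= min_overlap bp interval overlap)."""
    if indexes is None:
        indexes = {k: IntervalIndex(ps.intervals) for k, ps in peaksets.items()}
    out = {}
    for key in peaksets:
        if key not in indexes:
            raise KeyError(f"unknown dataset key {key!r}")
        out[key] = indexes[key].overlaps(site, min_overlap)
    return out


def _build_indexes(
    peaksets: Mapping[str, PeakSet], keys: Iterable[str]
) -> dict[str, IntervalIndex]:
    indexes = {}
    for key in keys:
        if key not in peaksets:
            raise KeyError(f"unknown dataset key {key!r}")
        indexes[key] = IntervalIndex(peaksets[key].intervals)
    return indexes


def classify(
    peaksets: Mapping[str, PeakSet],
    definitions: Sequence[CategoryDefinition],
    min_overlap: int = 1,
) -> ClassifiedSites:
    """Evaluate every category recipe and resolve conflicts by priority.

    For each definition, every anchor peak overlapped by all include sets
    and by no exclude set is a candidate. A peak interval matching several
    definitions goes to the earliest one (list order = priority) and is
    logged. Output category site lists are pairwise disjoint.
    """
    needed = {k for d in definitions for k in d.keys}
    indexes = _build_indexes(peaksets, needed)

    candidates: dict[GenomicInterval, list[tuple[int, Peak]]] = {}
    anchor_peaks: dict[str, list[Peak]] = {}
    matched: dict[str, set[GenomicInterval]] = {d.name: set() for d in definitions}
    for di, d in enumerate(definitions):
        anchors = peaksets[d.anchor]
        anchor_peaks.setdefault(d.anchor, list(anchors))
        if len(anchors) == 0:
            warnings.warn(f"category {d.name!r}: anchor set {d.anchor!r} is empty")
        include = [k for k in d.include if k != d.anchor]
        for peak in anchors:
            iv = peak.interval
            if not all(indexes[k].overlaps(iv, min_overlap) for k in include):
                continue
            if any(indexes[k].overlaps(iv, min_overlap) for k in d.exclude):
                continue
            candidates.setdefault(iv, []).append((di, peak))
            matched[d.name].add(iv)

    sites: dict[str, list[Peak]] = {d.name: [] for d in definitions}
    conflicts: list[ConflictRecord] = []
    assigned: set[GenomicInterval] = set()
    for iv, hits in candidates.items():
        hits.sort(key=lambda h: h[0])
        win_i, win_peak = hits[0]
        winner = definitions[win_i].name
        sites[winner].append(win_peak)
        assigned.add(iv)
        losers = tuple(
            definitions[i].name for i, _ in hits[1:] if definitions[i].name != winner
        )
        if losers:
            conflicts.append(ConflictRecord(iv, winner, losers))

    for name in sites:
        sites[name].sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))

    unclassified = {
        anchor: [p for p in peaks if p.interval not in assigned]
        for anchor, peaks in anchor_peaks.items()
    }
    return ClassifiedSites(sites=sites, conflicts=conflicts, unclassified=unclassified)


# ---------------------------------------------------------------------------
# default definitions

GERMLINE, SOMA, INTESTINE = "germline", "soma", "intestine"

DEFAULT_DATASET_KEYS: tuple[str, ...] = (
    f"EFL-1@{GERMLINE}",
    f"DPL-1@{GERMLINE}",
    f"EFL-1@{SOMA}",
    f"DPL-1@{SOMA}",
    f"LIN-35@{SOMA}",
    f"EFL-1@{INTESTINE}",
    f"DPL-1@{INTESTINE}",
    f"LIN-35@{INTESTINE}",
    f"HPL-2@{INTESTINE}",
)


def default_category_definitions(
    available: Iterable[str] | Mapping[str, PeakSet] | None = None,
) -> list[CategoryDefinition]:
    """The four default tissue categories, in priority order.

    Priority: germline-specific, soma-specific, intestine-specific,
    broadly bound. If ``available`` is given, every dataset key the
    definitions reference must be present; missing keys raise with a
    full list of what is absent.
    """
    g_efl1, g_dpl1 = f"EFL-1@{GERMLINE}", f"DPL-1@{GERMLINE}"
    s_efl1, s_dpl1, s_lin35 = (
        f"EFL-1@{SOMA}",
        f"DPL-1@{SOMA}",
        f"LIN-35@{SOMA}",
    )
    i_efl1, i_dpl1 = f"EFL-1@{INTESTINE}", f"DPL-1@{INTESTINE}"
    i_lin35, i_hpl2 = f"LIN-35@{INTESTINE}", f"HPL-2@{INTESTINE}"

    definitions = [
        CategoryDefinition(
            name="germline_specific",
            anchor=g_efl1,
            include=(g_efl1, g_dpl1),
            exclude=(s_dpl1,),
        ),
        CategoryDefinition(
            name="soma_specific",
            anchor=s_efl1,
            include=(s_efl1, s_dpl1, s_lin35),
            exclude=(g_efl1, i_hpl2),
        ),
        CategoryDefinition(
            name="intestine_specific",
            anchor=i_lin35,
            include=(i_lin35, i_hpl2),
            exclude=(s_efl1, i_efl1),
        ),
        CategoryDefinition(
            name="broadly_bound",
            anchor=s_lin35,
            include=(g_efl1, i_dpl1, s_lin35),
            exclude=(),
        ),
    ]
    if available is not None:
        have = set(available)
        needed = {k for d in definitions for k in d.keys}
        missing = sorted(needed - have)
        if missing:
            raise KeyError(
                f"missing required dataset key(s): {', '.join(missing)}"
            )
    return definitions
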