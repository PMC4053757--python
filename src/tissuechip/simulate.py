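"""Synthetic genomes, peak sets, gene lists and read tracks with planted
ground truth.

The generator emulates the input classes of a multi-factor, multi-tissue
ChIP-seq study in a worm-like genome (five autosomes plus an X,
~100 Mb, ~20,000 genes):

* a gene annotation with uniformly placed non-overlapping genes, each
  independently flagged germline-expressed (genome-wide fraction 0.105,
  down-weighted on the X with autosomes rescaled so the genome-wide
  expectation is unchanged);
* nine factor@tissue peak sets in which sites of four tissue categories
  are planted: each site's anchor interval is placed at a controlled TSS
  distance from a target gene drawn with a category-specific germline
  bias and X-chromosome odds multiplier, overlapping peaks are emitted
  into exactly the category's include datasets, and degradation
  (include-peak dropout, spurious peaks) is applied afterwards;
* replicate read tracks with gamma-Poisson window counts whose
  inter-replicate Pearson correlation has the closed form
  r = phi*mu / (1 + phi*mu);
* regulated-gene lists and a GMT term map with known overlap counts.

Planted sites occupy globally disjoint padded slots, so at zero noise
no site overlaps any peak of another category: classification recovers
the planted labels exactly.

Everything is a pure function of (config, seed); per-module random
sub-streams are derived from the master seed by stable labels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import bisect
import math

import numpy as np

from .classification import (
    CategoryDefinition,
    ClassifiedSites,
    default_category_definitions,
)
from .concordance import ReadTrack, tile_windows
from .model import (
    GenomeAnnotation,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
)

__all__ = [
    "SimConfig",
    "PlantedSite",
    "SimTruth",
    "simulate_genome",
    "simulate_binding",
    "simulate_reads",
    "make_regulated_list",
    "simulate_regulated_lists",
    "simulate_terms",
    "score_recovery",
    "write_dataset",
]

# C. elegans-like chromosome grid (name, length bp, is_X)
_DEFAULT_CHROMS: tuple[tuple[str, int, bool], ...] = (
    ("I", 15_072_000, False),
    ("II", 15_279_000, False),
    ("III", 13_784_000, False),
    ("IV", 17_494_000, False),
    ("V", 20_924_000, False),
    ("X", 17_719_000, True),
)


def _default_sites() -> dict[str, int]:
    return {
        "germline_specific": 415,
        "soma_specific": 282,
        "intestine_specific": 656,
        "broadly_bound": 1419,
    }


def _default_widths() -> dict[str, float]:
    # intestine-specific sites cover roughly twice the nucleotides of the rest
    return {
        "germline_specific": 400.0,
        "soma_specific": 400.0,
        "intestine_specific": 800.0,
        "broadly_bound": 400.0,
    }


def _default_germline_bias() -> dict[str, float]:
    # germline/soma/broad targets enriched for germline expression,
    # intestine depleted
    return {
        "germline_specific": 0.45,
        "soma_specific": 0.30,
        "intestine_specific": 0.02,
        "broadly_bound": 0.30,
    }


def _default_x_multiplier() -> dict[str, float]:
    # intestine targets enriched on the X, the rest depleted
    return {
        "germline_specific": 0.25,
        "soma_specific": 0.5,
        "intestine_specific": 3.0,
        "broadly_bound": 0.5,
    }


def _default_distance_mixture() -> dict[str, float]:
    return {"high": 0.70, "low": 0.15, "unassigned": 0.15}


def _default_regulated_lists() -> tuple[tuple[str, str, int, int], ...]:
    # (name, category, list size n, planted overlap k); the default echoes
    # a 74-gene down-regulated gonad list sharing 36 genes with the
    # germline-specific targets
    return (("gonad_down", "germline_specific", 74, 36),)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the defaults used throughout."""

    seed: int = 0
    chromosomes: tuple[tuple[str, int, bool], ...] = _DEFAULT_CHROMS
    genes_per_chrom: int = 3300
    gene_length_mean: float = 2000.0
    gene_length_sigma: float = 0.6
    germline_fraction: float = 0.105
    germline_x_multiplier: float = 0.12
    sites_per_category: dict[str, int] = field(default_factory=_default_sites)
    width_mean: dict[str, float] = field(default_factory=_default_widths)
    width_sigma: float = 0.35
    category_germline_bias: dict[str, float] = field(
        default_factory=_default_germline_bias
    )
    category_x_multiplier: dict[str, float] = field(
        default_factory=_default_x_multiplier
    )
    target_distance_distribution: dict[str, float] = field(
        default_factory=_default_distance_mixture
    )
    high_dist: int = 500
    low_dist: int = 2000
    dropout: float = 0.0
    spurious_rate: float = 0.0
    regulated_lists: tuple[tuple[str, str, int, int], ...] = field(
        default_factory=_default_regulated_lists
    )
    n_background_terms: int = 25
    read_depth_mu: float = 100.0
    phi: float = 0.1
    window: int = 100

    def __post_init__(self) -> None:
        for name, p in (
            ("germline_fraction", self.germline_fraction),
            ("dropout", self.dropout),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if any(n < 0 for n in self.sites_per_category.values()):
            raise ValueError("site counts must be non-negative")
        if any(w <= 0 for w in self.width_mean.values()):
            raise ValueError("width means must be positive")
        tot = sum(self.target_distance_distribution.values())
        if not math.isclose(tot, 1.0, rel_tol=1e-9):
            raise ValueError("target_distance_distribution must sum to 1")

    def with_overrides(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _rng(seed: int, label: str) -> np.random.Generator:
    """Sub-stream generator derived from the master seed by a stable label."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> tuple[GenomeAnnotation, list[str]]:
    """Place genes uniformly without overlap; flag germline genes.

    The per-gene germline probability is rescaled between autosomes and
    the X so the genome-wide expectation equals ``germline_fraction``
    while the X carries ``germline_x_multiplier`` times the autosomal
    per-gene odds.
    """
    rng = _rng(config.seed, "genome")
    n = config.genes_per_chrom
    mu_log = math.log(config.gene_length_mean) - config.gene_length_sigma**2 / 2

    genes: list[GeneModel] = []
    sizes: dict[str, int] = {}
    x_chroms: list[str] = []
    x_flags: list[bool] = []
    for chrom, length, is_x in config.chromosomes:
        sizes[chrom] = length
        if is_x:
            x_chroms.append(chrom)
        lengths = np.exp(
            rng.normal(mu_log, config.gene_length_sigma, n)
        ).astype(np.int64)
        lengths = np.clip(lengths, 200, 50_000)
        total = int(lengths.sum())
        free = length - total
        if free <= 0:
            raise ValueError(
                f"{n} genes (total {total} bp) cannot fit on {chrom} "
                f"({length} bp) without overlap; use longer chromosomes"
            )
        cuts = np.sort(rng.uniform(0, free, n)).astype(np.int64)
        starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))
        strands = rng.choice(["+", "-"], n)
        for i in range(n):
            gid = f"g{chrom}.{i + 1}"
            span = GenomicInterval(chrom, int(starts[i]), int(starts[i] + lengths[i]))
            genes.append(GeneModel(gid, chrom, str(strands[i]), span))
            x_flags.append(is_x)

    x_flags_arr = np.array(x_flags)
    n_x = int(x_flags_arr.sum())
    n_auto = len(genes) - n_x
    m = config.germline_x_multiplier
    p_auto = config.germline_fraction * len(genes) / (n_auto + m * n_x)
    if p_auto > 1.0:
        raise ValueError("germline_fraction/x_multiplier combination infeasible")
    probs = np.where(x_flags_arr, m * p_auto, p_auto)
    is_germ = rng.random(len(genes)) < probs
    germline = [g.gene_id for g, flag in zip(genes, is_germ) if flag]
    annotation = GenomeAnnotation(sizes, genes, x_chromosomes=x_chroms)
    return annotation, germline


# ---------------------------------------------------------------------------
# binding sites


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted binding site."""

    site_id: str
    category: str
    anchor: GenomicInterval
    target_gene: str | None
    tier: str  # 'high' | 'low' | 'unassigned'
    distance: int | None
    germline: bool
    on_x: bool


@dataclass
class SimTruth:
    """Planted labels against which pipeline recovery is scored."""

    sites: list[PlantedSite]
    planted_peak_names: dict[str, set[str]]
    dropped_peak_names: dict[str, set[str]]
    spurious_peak_names: dict[str, set[str]]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.category] = counts.get(s.category, 0) + 1
        return counts

    def sites_in(self, category: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.category == category]

    def target_genes(
        self, category: str, tiers: Iterable[str] = ("high", "low")
    ) -> set[str]:
        wanted = set(tiers)
        return {
            s.target_gene
            for s in self.sites
            if s.category == category and s.tier in wanted and s.target_gene
        }

    def site_by_interval(self) -> dict[GenomicInterval, PlantedSite]:
        return {s.anchor: s for s in self.sites}


class _Occupied:
    """Sorted disjoint blocked regions per chromosome."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        blocks = self._by_chrom.get(chrom)
        if not blocks:
            return True
        i = bisect.bisect_left(blocks, (start, start))
        if i < len(blocks) and blocks[i][0] < end:
            return False
        if i > 0 and blocks[i - 1][1] > start:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        bisect.insort(self._by_chrom.setdefault(chrom, []), (start, end))


def _gene_weights(
    annotation: GenomeAnnotation,
    germline: set[str],
    bias: float,
    x_mult: float,
    gene_ids: list[str],
) -> np.ndarray:
    """Per-gene sampling weights achieving P(germline) = bias exactly and
    X odds scaled by x_mult within each germline stratum."""
    is_germ = np.array([g in germline for g in gene_ids])
    on_x = np.array([annotation.is_x(annotation.genes[g].chrom) for g in gene_ids])
    w = np.where(on_x, x_mult, 1.0)
    weights = np.zeros(len(gene_ids))
    for stratum, mass in ((is_germ, bias), (~is_germ, 1.0 - bias)):
        total = w[stratum].sum()
        if total > 0:
            weights[stratum] = mass * w[stratum] / total
        elif mass > 0:
            raise ValueError("no genes available in a required stratum")
    return weights / weights.sum()


def simulate_binding(
    config: SimConfig,
    annotation: GenomeAnnotation,
    germline: Sequence[str],
    definitions: Sequence[CategoryDefinition] | None = None,
) -> tuple[dict[str, PeakSet], SimTruth]:
    """Plant category-labelled sites and emit the factor@tissue peak sets.

    Each planted site chooses a target gene (respecting the category's
    germline bias and X multiplier), places its anchor at a TSS distance
    drawn from the configured high/low/unassigned mixture, draws a
    lognormal width, and emits overlapping peaks into exactly the
    category's include datasets. Dropout and spurious peaks are applied
    afterwards; the returned truth describes the pre-degradation state.
    """
    if definitions is None:
        definitions = default_category_definitions()
    def_by_name = {d.name: d for d in definitions}
    for cat in config.sites_per_category:
        if cat not in def_by_name:
            raise KeyError(f"sites_per_category references unknown category {cat!r}")
    dataset_keys = sorted({k for d in definitions for k in d.keys})

    rng = _rng(config.seed, "binding")
    germ_set = set(germline)
    gene_ids = sorted(annotation.genes)
    tss_index = annotation.tss_index()
    chrom_names = [c for c, _, _ in config.chromosomes]
    chrom_lengths = np.array([l for _, l, _ in config.chromosomes], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    occupied = _Occupied()
    peaks_by_key: dict[str, list[Peak]] = {k: [] for k in dataset_keys}
    truth_sites: list[PlantedSite] = []
    planted_names: dict[str, set[str]] = {k: set() for k in dataset_keys}

    mix_names = list(config.target_distance_distribution)
    mix_p = np.array([config.target_distance_distribution[t] for t in mix_names])

    for cat, n_sites in config.sites_per_category.items():
        d = def_by_name[cat]
        weights = _gene_weights(
            annotation,
            germ_set,
            config.category_germline_bias[cat],
            config.category_x_multiplier[cat],
            gene_ids,
        )
        wmean = config.width_mean[cat]
        mu_log = math.log(wmean) - config.width_sigma**2 / 2
        for i in range(n_sites):
            tier = mix_names[int(rng.choice(len(mix_names), p=mix_p))]
            placed = None
            for _ in range(40):  # resample the gene if placement keeps failing
                if tier == "unassigned":
                    placed = _place_far_site(
                        rng, config, tss_index, chrom_names, chrom_p,
                        annotation, occupied, mu_log,
                    )
                else:
                    gi = int(rng.choice(len(gene_ids), p=weights))
                    placed = _place_near_site(
                        rng, config, annotation.genes[gene_ids[gi]],
                        annotation, occupied, mu_log, tier,
                    )
                if placed is not None:
                    break
            if placed is None:
                raise RuntimeError(
                    f"could not place site {i} of category {cat}; "
                    "genome too crowded"
                )
            anchor, gene_id, dist = placed
            site_id = f"{cat}:{i:05d}"
            truth_sites.append(
                PlantedSite(
                    site_id=site_id,
                    category=cat,
                    anchor=anchor,
                    target_gene=gene_id,
                    tier=tier,
                    distance=dist,
                    germline=gene_id in germ_set if gene_id else False,
                    on_x=annotation.is_x(anchor.chrom),
                )
            )
            # anchor peak + jittered companions in the other include sets
            for key in d.include:
                if key == d.anchor:
                    iv = anchor
                    name = site_id
                else:
                    w2 = max(50, int(round(anchor.width * rng.uniform(0.85, 1.15))))
                    shift = int(round(rng.uniform(-0.3, 0.3) * anchor.width))
                    s = max(0, anchor.start + shift)
                    iv = GenomicInterval(anchor.chrom, s, s + w2)
                    name = f"{site_id}|{key}"
                neglog_q = rng.uniform(3.5, 60.0)
                peaks_by_key[key].append(
                    Peak(
                        interval=iv,
                        name=name,
                        score=float(round(rng.uniform(100, 1000))),
                        strand=".",
                        signal=float(rng.uniform(5, 50)),
                        pvalue=neglog_q + 1.0,
                        qvalue=10.0 ** (-neglog_q),
                        summit=iv.width // 2,
                    )
                )
                planted_names[key].add(name)

    # degradation: include-peak dropout, then spurious peaks
    dropped: dict[str, set[str]] = {k: set() for k in dataset_keys}
    spurious: dict[str, set[str]] = {k: set() for k in dataset_keys}
    for key in dataset_keys:
        if config.dropout > 0:
            kept = []
            for p in peaks_by_key[key]:
                if rng.random() < config.dropout:
                    dropped[key].add(p.name)
                else:
                    kept.append(p)
            peaks_by_key[key] = kept
        n_spur = int(rng.poisson(config.spurious_rate))
        for j in range(n_spur):
            ci = int(rng.choice(len(chrom_names), p=chrom_p))
            chrom, length = chrom_names[ci], int(chrom_lengths[ci])
            w = max(50, int(np.exp(rng.normal(math.log(400.0), config.width_sigma))))
            s = int(rng.integers(0, max(1, length - w)))
            name = f"spurious|{key}|{j}"
            neglog_q = rng.uniform(3.1, 10.0)
            peaks_by_key[key].append(
                Peak(
                    interval=GenomicInterval(chrom, s, s + w),
                    name=name,
                    score=50.0,
                    qvalue=10.0 ** (-neglog_q),
                )
            )
            spurious[key].add(name)

    peaksets = {}
    for key in dataset_keys:
        factor, tissue = key.split("@", 1)
        peaksets[key] = PeakSet(factor=factor, tissue=tissue, peaks=peaks_by_key[key])
    truth = SimTruth(
        sites=truth_sites,
        planted_peak_names=planted_names,
        dropped_peak_names=dropped,
        spurious_peak_names=spurious,
    )
    return peaksets, truth


def _slot_pad(width: int) -> int:
    # companion peaks extend at most ~0.45 * width beyond the anchor
    return width // 2 + 10


def _try_block(
    occupied: _Occupied, annotation: GenomeAnnotation, iv: GenomicInterval
) -> bool:
    pad = _slot_pad(iv.width)
    lo, hi = iv.start - pad, iv.end + pad
    if lo < 0 or hi > annotation.chromosomes[iv.chrom]:
        return False
    if not occupied.is_free(iv.chrom, lo, hi):
        return False
    occupied.add(iv.chrom, lo, hi)
    return True


def _place_near_site(
    rng: np.random.Generator,
    config: SimConfig,
    gene: GeneModel,
    annotation: GenomeAnnotation,
    occupied: _Occupied,
    mu_log: float,
    tier: str,
) -> tuple[GenomicInterval, str, int] | None:
    tss = gene.tss
    for _ in range(8):
        w = max(50, int(np.exp(rng.normal(mu_log, config.width_sigma))))
        if tier == "high":
            d = int(rng.integers(0, config.high_dist))
        else:
            d = int(rng.integers(config.high_dist, config.low_dist + 1))
        if d == 0:
            start = tss - int(rng.integers(0, w))
        elif rng.random() < 0.5:
            start = tss - d + 1 - w  # upstream: nearest base is end - 1
        else:
            start = tss + d  # downstream: nearest base is start
        if start < 0:
            continue
        iv = GenomicInterval(gene.chrom, start, start + w)
        if _try_block(occupied, annotation, iv):
            return iv, gene.gene_id, d
    return None


def _place_far_site(
    rng: np.random.Generator,
    config: SimConfig,
    tss_index,
    chrom_names: list[str],
    chrom_p: np.ndarray,
    annotation: GenomeAnnotation,
    occupied: _Occupied,
    mu_log: float,
) -> tuple[GenomicInterval, None, None] | None:
    margin = config.low_dist + 1
    for _ in range(60):
        ci = int(rng.choice(len(chrom_names), p=chrom_p))
        chrom = chrom_names[ci]
        length = annotation.chromosomes[chrom]
        w = max(50, int(np.exp(rng.normal(mu_log, config.width_sigma))))
        start = int(rng.integers(0, max(1, length - w)))
        iv = GenomicInterval(chrom, start, start + w)
        entry = tss_index.get(chrom)
        if entry is not None:
            positions = entry[0]
            lo = int(np.searchsorted(positions, iv.start - margin, side="left"))
            hi = int(np.searchsorted(positions, iv.end - 1 + margin, side="right"))
            if hi > lo:  # a TSS within the unassignable margin
                continue
        if _try_block(occupied, annotation, iv):
            return iv, None, None
    return None


# ---------------------------------------------------------------------------
# read tracks


def simulate_reads(
    peaks: PeakSet,
    config: SimConfig,
    label: str = "rep",
) -> tuple[ReadTrack, ReadTrack]:
    """Two replicate read tracks over the peaks' tiled windows.

    Per window a latent intensity lambda ~ Gamma(mean mu, variance
    phi*mu^2) is drawn once, then each replicate's count ~ Poisson(lambda)
    and read 5' positions uniform in the window. The induced replicate
    correlation is phi*mu / (1 + phi*mu); phi = 0 gives independent
    Poisson replicates.
    """
    if config.read_depth_mu <= 0:
        raise ValueError("read_depth_mu must be > 0")
    if config.phi < 0:
        raise ValueError("phi must be >= 0")
    rng = _rng(config.seed, f"reads:{label}")
    windows = tile_windows(peaks, config.window)
    mu, phi = config.read_depth_mu, config.phi
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu, size=len(windows))
    else:
        lam = np.full(len(windows), mu)
    tracks = []
    for rep in (1, 2):
        counts = rng.poisson(lam)
        reads: list[tuple[str, int]] = []
        for w, c in zip(windows, counts):
            if c > 0:
                for pos in rng.integers(w.start, w.end, int(c)):
                    reads.append((w.chrom, int(pos)))
        tracks.append(ReadTrack(label=f"{label}{rep}", reads=reads))
    return tracks[0], tracks[1]


# ---------------------------------------------------------------------------
# gene lists and terms


def make_regulated_list(
    truth: SimTruth,
    annotation: GenomeAnnotation,
    category: str,
    n_list: int,
    n_overlap: int,
    rng: np.random.Generator,
    tiers: Iterable[str] = ("high", "low"),
) -> list[str]:
    """A "regulated genes" list with a planted overlap against one
    category's target genes: exactly n_overlap targets plus background."""
    targets = sorted(truth.target_genes(category, tiers))
    if n_overlap > n_list:
        raise ValueError("n_overlap cannot exceed n_list")
    if n_overlap > len(targets):
        raise ValueError(
            f"requested overlap {n_overlap} exceeds the {len(targets)} "
            f"available {category} targets"
        )
    chosen = list(rng.choice(targets, size=n_overlap, replace=False))
    background_pool = sorted(set(annotation.genes) - set(targets))
    background = list(
        rng.choice(background_pool, size=n_list - n_overlap, replace=False)
    )
    out = chosen + background
    rng.shuffle(out)
    return out


def simulate_regulated_lists(
    truth: SimTruth, annotation: GenomeAnnotation, config: SimConfig
) -> dict[str, list[str]]:
    rng = _rng(config.seed, "regulated")
    return {
        name: make_regulated_list(truth, annotation, category, n_list, n_overlap, rng)
        for name, category, n_list, n_overlap in config.regulated_lists
    }


def simulate_terms(
    truth: SimTruth, annotation: GenomeAnnotation, config: SimConfig
) -> dict[str, set[str]]:
    """A GMT-style term map: one enriched module per category (60% of its
    targets plus background genes) and random background terms."""
    rng = _rng(config.seed, "terms")
    all_genes = sorted(annotation.genes)
    terms: dict[str, set[str]] = {}
    for cat in truth.category_counts():
        targets = sorted(truth.target_genes(cat))
        n_take = max(1, int(0.6 * len(targets)))
        take = set(rng.choice(targets, size=n_take, replace=False))
        noise = set(rng.choice(all_genes, size=max(5, n_take // 4), replace=False))
        terms[f"{cat}_module"] = take | noise
    for j in range(config.n_background_terms):
        size = int(rng.integers(20, 200))
        terms[f"background_{j:03d}"] = set(
            rng.choice(all_genes, size=size, replace=False)
        )
    return terms


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(truth: SimTruth, classified: ClassifiedSites):
    """Planted-vs-recovered confusion matrix and per-category recovery.

    Rows are planted categories, columns the assigned categories plus
    'none' (planted sites recovered in no category). Classified sites
    whose intervals match no planted anchor are tallied separately.
    """
    import pandas as pd

    planted = truth.site_by_interval()
    categories = list(dict.fromkeys(s.category for s in truth.sites))
    assigned_names = list(classified.sites)
    cols = list(dict.fromkeys([*assigned_names, "none"]))
    matrix = pd.DataFrame(0, index=categories, columns=cols, dtype=int)
    unplanted = 0
    seen: set[GenomicInterval] = set()
    for name, peaks in classified.sites.items():
        for p in peaks:
            site = planted.get(p.interval)
            if site is None:
                unplanted += 1
            else:
                matrix.loc[site.category, name] += 1
                seen.add(p.interval)
    for iv, site in planted.items():
        if iv not in seen:
            matrix.loc[site.category, "none"] += 1
    recovery = {
        cat: (matrix.loc[cat, cat] / matrix.loc[cat].sum())
        if matrix.loc[cat].sum() > 0 and cat in matrix.columns
        else math.nan
        for cat in categories
    }
    return {"confusion": matrix, "recovery": recovery, "unplanted_sites": unplanted}


# ---------------------------------------------------------------------------
# on-disk fixture emission


def write_dataset(outdir: str | Path, config: SimConfig) -> dict[str, object]:
    """Emit a complete synthetic study to disk.

    Writes GFF3 + chrom.sizes, one narrowPeak per dataset, the germline
    and regulated gene lists, a GMT term map, replicate read-track BEDs
    for the germline EFL-1 dataset, truth tables (TSV), and a ready-made
    run-config YAML. Deterministic given the config.
    """
    import pandas as pd
    import yaml

    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)

    annotation, germline = simulate_genome(config)
    peaksets, truth = simulate_binding(config, annotation, germline)
    regulated = simulate_regulated_lists(truth, annotation, config)
    terms = simulate_terms(truth, annotation, config)

    tio.write_gff3(annotation, outdir / "genes.gff3")
    tio.write_chrom_sizes(annotation.chromosomes, outdir / "genome.chrom.sizes")
    tio.write_gene_list(germline, outdir / "germline_genes.txt")
    peak_paths = {}
    for key, ps in peaksets.items():
        path = outdir / "peaks" / f"{key}.narrowPeak"
        tio.write_narrowpeak(ps, path)
        peak_paths[key] = str(path)
    for name, genes in regulated.items():
        tio.write_gene_list(genes, outdir / f"regulated_{name}.txt")
    tio.write_gmt(terms, outdir / "terms.gmt")

    track_key = "EFL-1@germline"
    rep1, rep2 = simulate_reads(peaksets[track_key], config, label=track_key)
    tio.write_read_track(rep1, outdir / "reads_rep1.bed")
    tio.write_read_track(rep2, outdir / "reads_rep2.bed")

    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "category": s.category,
                "chrom": s.anchor.chrom,
                "start": s.anchor.start,
                "end": s.anchor.end,
                "target_gene": s.target_gene or "",
                "tier": s.tier,
                "distance": "" if s.distance is None else s.distance,
                "germline": int(s.germline),
                "on_x": int(s.on_x),
            }
            for s in truth.sites
        ]
    ).to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)

    run_config = {
        "datasets": peak_paths,
        "annotation": str(outdir / "genes.gff3"),
        "chrom_sizes": str(outdir / "genome.chrom.sizes"),
        "germline_genes": str(outdir / "germline_genes.txt"),
        "regulated_lists": {
            name: str(outdir / f"regulated_{name}.txt") for name in regulated
        },
        "terms": str(outdir / "terms.gmt"),
        "read_tracks": {
            track_key: [str(outdir / "reads_rep1.bed"), str(outdir / "reads_rep2.bed")]
        },
        "categories": "default",
        "outdir": str(outdir / "results"),
        "seed": config.seed,
    }
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)

    return {
        "annotation": annotation,
        "germline": germline,
        "peaksets": peaksets,
        "truth": truth,
        "regulated": regulated,
        "terms": terms,
        "run_config": str(outdir / "run_config.yaml"),
    }
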