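"""End-to-end orchestration: config, validation, staged execution, report.

A run loads the per-dataset peak files (applying the q-value filter),
merge-normalizes them, classifies sites into tissue categories, assigns
candidate target genes by TSS distance, and characterizes every category
(width, genomic context, unassignable fraction, germline enrichment,
chromosomal distribution, regulated-list overlaps, term enrichment),
optionally adding replicate concordance. All tables are written as TSV
and the machine-readable summary as JSON with stable key order and
floats at 10 significant digits, so reruns diff cleanly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .classification import (
    CategoryDefinition,
    ClassifiedSites,
    classify,
    default_category_definitions,
)
from .concordance import concordance_summary
from .enrichment import (
    chromosome_distribution,
    germline_chisquare,
    germline_fraction,
    overlap_enrichment,
    term_enrichment,
)
from .io import (
    gmt_to_gene_terms,
    read_gene_list,
    read_genes,
    read_gmt,
    read_narrowpeak,
    read_read_track,
    write_bed,
)
from .model import PipelineParams
from .properties import genomic_context, unassignable_fraction, width_stats
from .targets import assign_targets, target_gene_set

__all__ = ["RunConfig", "validate", "run", "Pipeline"]

log = logging.getLogger("tissuechip")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    datasets: dict[str, str]
    annotation: str
    outdir: str
    chrom_sizes: str | None = None
    germline_genes: str | None = None
    universe: str | None = None
    regulated_lists: dict[str, str] = field(default_factory=dict)
    terms: str | None = None
    read_tracks: dict[str, list[str]] = field(default_factory=dict)
    categories: str | list[dict] = "default"
    params: PipelineParams = field(default_factory=PipelineParams)
    promoter_bp: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def definitions(self) -> list[CategoryDefinition]:
        if self.categories == "default":
            return default_category_definitions(self.datasets)
        return [
            CategoryDefinition(
                name=c["name"],
                anchor=c["anchor"],
                include=tuple(c["include"]),
                exclude=tuple(c.get("exclude", ())),
            )
            for c in self.categories
        ]


def validate(config: RunConfig) -> list[str]:
    """Check files and references; a non-empty issue list blocks the run."""
    issues: list[str] = []
    for key, path in config.datasets.items():
        if not Path(path).exists():
            issues.append(f"dataset {key!r}: missing peak file {path}")
    for name, path in [
        ("annotation", config.annotation),
        ("chrom_sizes", config.chrom_sizes),
        ("germline_genes", config.germline_genes),
        ("universe", config.universe),
        ("terms", config.terms),
    ]:
        if path is not None and not Path(path).exists():
            issues.append(f"{name}: missing file {path}")
    for name, path in config.regulated_lists.items():
        if not Path(path).exists():
            issues.append(f"regulated list {name!r}: missing file {path}")
    for key, tracks in config.read_tracks.items():
        if key not in config.datasets:
            issues.append(f"read_tracks references unknown dataset {key!r}")
        for t in tracks:
            if not Path(t).exists():
                issues.append(f"read track for {key!r}: missing file {t}")
    try:
        definitions = config.definitions()
    except (KeyError, ValueError) as exc:
        issues.append(f"categories: {exc}")
        definitions = []
    for d in definitions:
        for k in d.keys:
            if k not in config.datasets:
                issues.append(f"category {d.name!r}: unknown dataset key {k!r}")
    return issues


def _round_floats(obj: Any) -> Any:
    """Serialize floats at 10 significant digits for diffable reports."""
    if isinstance(obj, float):
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


class _Stage:
    """Context manager labelling failures with the stage that raised."""

    def __init__(self, name: str) -> None:
        self.name = name
        self.t0 = 0.0

    def __enter__(self) -> "_Stage":
        log.info("stage %s: start", self.name)
        self.t0 = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc is not None:
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, time.monotonic() - self.t0)


class Pipeline:
    """Lazily evaluated pipeline stages over one RunConfig."""

    def __init__(self, config: RunConfig) -> None:
        issues = validate(config)
        if issues:
            raise ValueError("invalid config: " + "; ".join(issues))
        self.config = config
        self.params = config.params

    @cached_property
    def annotation(self):
        with _Stage("annotation"):
            return read_genes(self.config.annotation, chrom_sizes=self.config.chrom_sizes)

    @cached_property
    def universe(self) -> set[str]:
        if self.config.universe:
            return set(read_gene_list(self.config.universe))
        return set(self.annotation.genes)

    @cached_property
    def germline(self) -> list[str] | None:
        if self.config.germline_genes:
            return read_gene_list(self.config.germline_genes)
        return None

    @cached_property
    def peaksets(self):
        with _Stage("load_peaks"):
            out = {}
            for key, path in self.config.datasets.items():
                factor, _, tissue = key.partition("@")
                ps = read_narrowpeak(
                    path,
                    q_threshold=self.params.q_threshold,
                    factor=factor,
                    tissue=tissue,
                )
                out[key] = ps
            return out

    @cached_property
    def classified(self) -> ClassifiedSites:
        with _Stage("classify"):
            return classify(
                self.peaksets, self.config.definitions(), self.params.min_overlap
            )

    @cached_property
    def assignments(self):
        with _Stage("assign_targets"):
            return {
                cat: assign_targets(
                    self.classified.intervals(cat),
                    self.annotation,
                    self.params,
                    category=cat,
                )
                for cat in self.classified.sites
            }

    def category_report(self, cat: str) -> dict:
        table = self.assignments[cat]
        peaks = self.classified.sites[cat]
        rep: dict[str, Any] = {"n_sites": len(peaks)}
        genes_all = target_gene_set(table)
        genes_high = target_gene_set(table, tiers=("high",))
        rep["target_genes_high"] = len(genes_high)
        rep["target_genes_all"] = len(genes_all)
        rep["unassignable_fraction"] = (
            unassignable_fraction(table) if table.n_sites else None
        )

        ws = width_stats({cat: peaks})[0]
        rep["width"] = {"n": ws.n, "mean": ws.mean, "se": ws.se}
        ctx = genomic_context(
            [p.interval for p in peaks],
            self.annotation,
            promoter_bp=self.config.promoter_bp,
            category=cat,
        )
        rep["context"] = {
            "promoter": ctx.promoter,
            "gene_body": ctx.gene_body,
            "intergenic": ctx.intergenic,
            "promoter_bp": ctx.promoter_bp,
        }

        if genes_all:
            if self.germline is not None:
                frac, enr = germline_fraction(genes_all, self.germline, self.universe)
                chi2, chi2_p = germline_chisquare(
                    genes_all, self.germline, self.universe
                )
                rep["germline"] = {
                    "fraction": frac,
                    "k": enr.k,
                    "n": enr.n,
                    "fold": enr.fold,
                    "p": enr.p,
                    "test": "hypergeometric",
                    "chi2": chi2,
                    "chi2_p": chi2_p,
                    "chi2_test": "pearson_chi_square",
                }
            chrom = chromosome_distribution(genes_all, self.annotation)
            rep["chromosome"] = {
                "chi2": chrom.chi2,
                "df": chrom.df,
                "p": chrom.p,
                "ratios": {
                    row.chrom: row.ratio for row in chrom.table.itertuples()
                },
            }
            if self.config.regulated_lists:
                rep["regulated"] = {}
                for name, path in self.config.regulated_lists.items():
                    reg = read_gene_list(path)
                    enr = overlap_enrichment(genes_all, reg, self.universe)
                    rep["regulated"][name] = {
                        "k": enr.k,
                        "n": enr.n,
                        "K": enr.K,
                        "N": enr.N,
                        "fold": enr.fold,
                        "p": enr.p,
                        "test": "hypergeometric",
                    }
            if self.config.terms:
                gene_terms = gmt_to_gene_terms(read_gmt(self.config.terms))
                rows = term_enrichment(
                    genes_all, gene_terms, self.universe, self.params
                )
                rep["terms"] = [
                    {
                        "term": r.term,
                        "k": r.k,
                        "n": r.n,
                        "K": r.K,
                        "N": r.N,
                        "fold": r.fold,
                        "p": r.p,
                    }
                    for r in rows
                ]
        return rep

    @cached_property
    def concordance(self) -> dict | str:
        if not self.config.read_tracks:
            return "skipped"
        with _Stage("concordance"):
            out = {}
            for key, paths in self.config.read_tracks.items():
                track_a = read_read_track(paths[0])
                track_b = read_read_track(paths[1])
                out[key] = concordance_summary(
                    self.peaksets[key],
                    track_a,
                    track_b,
                    width=self.params.window,
                    min_overlap=self.params.min_overlap,
                )
            return out

    def report(self) -> dict:
        with _Stage("report"):
            rep = {
                "tool": "tissuechip",
                "version": __version__,
                "seed": self.config.seed,
                "params": {
                    "q_threshold": self.params.q_threshold,
                    "high_dist": self.params.high_dist,
                    "low_dist": self.params.low_dist,
                    "window": self.params.window,
                    "min_overlap": self.params.min_overlap,
                    "promoter_bp": self.config.promoter_bp,
                },
                "datasets": {k: len(ps) for k, ps in self.peaksets.items()},
                "categories": {
                    cat: self.category_report(cat) for cat in self.classified.sites
                },
                "n_conflicts": len(self.classified.conflicts),
                "concordance": self.concordance,
            }
            return _round_floats(rep)

    def write_outputs(self) -> Path:
        outdir = Path(self.config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with _Stage("write_outputs"):
            for cat, peaks in self.classified.sites.items():
                write_bed(
                    [p.interval for p in peaks],
                    outdir / f"sites_{cat}.bed",
                    names=[p.name for p in peaks],
                )
            rows = []
            for cat, table in self.assignments.items():
                for a in table.assignments:
                    rows.append(
                        {
                            "chrom": a.site.chrom,
                            "start": a.site.start,
                            "end": a.site.end,
                            "category": cat,
                            "gene_id": a.gene_id,
                            "distance": a.distance,
                            "tier": a.tier,
                        }
                    )
            pd.DataFrame(
                rows,
                columns=["chrom", "start", "end", "category", "gene_id", "distance", "tier"],
            ).to_csv(outdir / "target_assignments.tsv", sep="\t", index=False)
            unassigned = [
                (cat, iv)
                for cat, table in self.assignments.items()
                for iv in table.unassigned_sites
            ]
            write_bed(
                [iv for _, iv in unassigned],
                outdir / "unassigned_sites.bed",
                names=[cat for cat, _ in unassigned],
            )
            pd.DataFrame(
                [
                    {
                        "chrom": c.interval.chrom,
                        "start": c.interval.start,
                        "end": c.interval.end,
                        "winner": c.winner,
                        "losers": ",".join(c.losers),
                    }
                    for c in self.classified.conflicts
                ],
                columns=["chrom", "start", "end", "winner", "losers"],
            ).to_csv(outdir / "conflicts.tsv", sep="\t", index=False)
            report = self.report()
            with open(outdir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
        return outdir


def run(config: RunConfig) -> dict:
    """Validate, execute every stage, write all artifacts; return the report."""
    pipe = Pipeline(config)
    pipe.write_outputs()
    return pipe.report()
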