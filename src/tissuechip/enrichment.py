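"""Gene-set statistics: hypergeometric over-representation, chromosomal
distribution with Pearson chi-square, germline-expression enrichment, and
generic term enrichment with fold/significance filters.

The over-representation statistic throughout is the upper-tail
hypergeometric probability P[X >= k] of drawing k or more marked genes
when sampling n genes from a universe of N containing K marked ones. It
is evaluated in log space so that the extreme tails such tests produce
(down to ~1e-300) remain finite and relatively accurate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist
from scipy.stats import false_discovery_control

from .model import GenomeAnnotation, PipelineParams

__all__ = [
    "EnrichmentResult",
    "ChromDistResult",
    "TermEnrichmentRow",
    "log_hypergeom_tail",
    "hypergeom_tail",
    "overlap_enrichment",
    "chromosome_distribution",
    "germline_fraction",
    "germline_chisquare",
    "term_enrichment",
]


def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Natural log of P[X >= k], X ~ Hypergeometric(N, K, n).

    Computed by summing gammaln-based log-pmf terms with logsumexp,
    which stays finite and relatively accurate for tails far below
    float underflow (e.g. N=20,000, K=400, n=100, k=100).
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if n > N or K > N:
        raise ValueError(f"need n <= N and K <= N (n={n}, K={K}, N={N})")
    hi = min(n, K)
    if k > hi:
        raise ValueError(f"impossible overlap: k={k} exceeds min(n, K)={hi}")
    lo_support = max(0, n - (N - K))
    if k <= lo_support:
        return 0.0  # the event is certain
    i = np.arange(k, hi + 1)
    log_pmf = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(logsumexp(log_pmf))


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k]."""
    return math.exp(log_hypergeom_tail(k, n, K, N))


@dataclass(frozen=True)
class EnrichmentResult:
    """Gene-set overlap test: k of n query genes hit a K-of-N reference."""

    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    log_p: float

    @classmethod
    def from_counts(cls, k: int, n: int, K: int, N: int, ease: bool = False) -> "EnrichmentResult":
        """Build fold and upper-tail p from the four counts.

        ``ease`` applies the DAVID-style EASE correction (test k-1
        instead of k, more conservative).
        """
        if n > 0 and K > 0:
            fold = (k / n) / (K / N)
        else:
            fold = math.nan
        k_test = max(k - 1, 0) if ease else k
        log_p = log_hypergeom_tail(k_test, n, K, N)
        return cls(k=k, n=n, K=K, N=N, fold=fold, p=math.exp(log_p), log_p=log_p)


def _restrict(genes: Collection[str], universe: set[str], what: str) -> set[str]:
    genes = set(genes)
    outside = genes - universe
    if outside:
        warnings.warn(
            f"{len(outside)} {what} gene(s) outside the universe were dropped"
        )
    return genes & universe


def overlap_enrichment(
    query: Collection[str],
    reference: Collection[str],
    universe: Collection[str],
    ease: bool = False,
) -> EnrichmentResult:
    """Over-representation of a reference gene set within a query set."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    q = _restrict(query, universe, "query")
    r = _restrict(reference, universe, "reference")
    return EnrichmentResult.from_counts(
        k=len(q & r), n=len(q), K=len(r), N=len(universe), ease=ease
    )


@dataclass
class ChromDistResult:
    """Observed vs expected target counts per chromosome.

    ``table`` has one row per chromosome with observed, expected (from
    the chromosome's share of annotated genes) and their ratio; the
    Pearson chi-square compares observed counts to expected with
    df = #chromosomes - 1.
    """

    table: pd.DataFrame
    chi2: float
    df: int
    p: float


def chromosome_distribution(
    targets: Collection[str], annotation: GenomeAnnotation
) -> ChromDistResult:
    """Ratio of observed to expected targets per chromosome plus chi-square."""
    targets = set(targets)
    missing = [t for t in targets if t not in annotation.genes]
    if missing:
        raise KeyError(f"target gene(s) not in annotation: {missing[:5]}")
    genes_per_chrom = {c: 0 for c in annotation.chromosomes}
    for g in annotation.genes.values():
        genes_per_chrom[g.chrom] += 1
    observed = {c: 0 for c in annotation.chromosomes}
    for t in targets:
        observed[annotation.genes[t].chrom] += 1
    for c, n_genes in genes_per_chrom.items():
        if n_genes == 0 and observed[c] > 0:
            raise ValueError(f"chromosome {c} has observed targets but no genes")
    chroms = [c for c in annotation.chromosomes if genes_per_chrom[c] > 0]
    total_genes = sum(genes_per_chrom[c] for c in chroms)
    n_targets = len(targets)
    rows = []
    chi2 = 0.0
    for c in chroms:
        e = n_targets * genes_per_chrom[c] / total_genes
        o = observed[c]
        ratio = o / e if e > 0 else math.nan
        if e > 0:
            chi2 += (o - e) ** 2 / e
        rows.append(
            {
                "chrom": c,
                "is_x": annotation.is_x(c),
                "genes": genes_per_chrom[c],
                "observed": o,
                "expected": e,
                "ratio": ratio,
            }
        )
    df = len(chroms) - 1
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else math.nan
    return ChromDistResult(table=pd.DataFrame(rows), chi2=chi2, df=df, p=p)


def germline_fraction(
    targets: Collection[str],
    germline: Collection[str],
    universe: Collection[str],
) -> tuple[float, EnrichmentResult]:
    """Fraction of targets on the germline-expressed list, plus enrichment.

    Returns (|targets ∩ germline| / |targets|, hypergeometric
    EnrichmentResult against the universe baseline).
    """
    targets = set(targets)
    if not targets:
        raise ValueError("empty target set")
    result = overlap_enrichment(targets, germline, universe)
    fraction = result.k / result.n if result.n else math.nan
    return fraction, result


def germline_chisquare(
    targets: Collection[str],
    germline: Collection[str],
    universe: Collection[str],
) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2
    table of (target vs rest of universe) x (germline vs not)."""
    universe = set(universe)
    targets = set(targets) & universe
    germline = set(germline) & universe
    if not targets or len(targets) == len(universe):
        raise ValueError("targets must be a proper non-empty subset of the universe")
    a = len(targets & germline)
    b = len(targets) - a
    c = len(germline) - a
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(chi2_dist.sf(chi2, 1))


@dataclass(frozen=True)
class TermEnrichmentRow:
    term: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    q: float | None = None


def term_enrichment(
    targets: Collection[str],
    gene_terms: Mapping[str, Collection[str]],
    universe: Collection[str],
    params: PipelineParams | None = None,
    ease: bool = False,
    fdr: bool = False,
) -> list[TermEnrichmentRow]:
    """Per-term over-representation with the report filters applied.

    Terms come from a gene -> terms map (see io.gmt_to_gene_terms for
    GMT input). Rows with fold > params.term_min_fold and raw
    p < params.term_alpha are kept, sorted by p ascending (ties broken
    by fold descending then term id) and truncated to params.term_top.
    ``fdr`` adds Benjamini-Hochberg q-values (computed over all terms
    before filtering); filtering itself uses raw p, matching reports
    that quote uncorrected P.
    """
    if params is None:
        params = PipelineParams()
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    targets = set(targets) & universe
    term_genes: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        if gene not in universe:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    rows: list[TermEnrichmentRow] = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        res = EnrichmentResult.from_counts(
            k=len(targets & genes),
            n=len(targets),
            K=len(genes),
            N=len(universe),
            ease=ease,
        )
        rows.append(
            TermEnrichmentRow(term, res.k, res.n, res.K, res.N, res.fold, res.p)
        )
    if fdr and rows:
        qs = false_discovery_control([r.p for r in rows])
        rows = [
            TermEnrichmentRow(r.term, r.k, r.n, r.K, r.N, r.fold, r.p, float(q))
            for r, q in zip(rows, qs)
        ]
    kept = [
        r
        for r in rows
        if not math.isnan(r.fold)
        and r.fold > params.term_min_fold
        and r.p < params.term_alpha
    ]
    kept.sort(key=lambda r: (r.p, -r.fold, r.term))
    return kept[: params.term_top]
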