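"""Gene-set statistics: hypergeometric tail, overlap enrichment,
chromosomal distribution chi-square, germline fraction, term filters."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from tissuechip.enrichment import (
    EnrichmentResult,
    chromosome_distribution,
    germline_chisquare,
    germline_fraction,
    hypergeom_tail,
    log_hypergeom_tail,
    overlap_enrichment,
    term_enrichment,
)
from tissuechip.model import PipelineParams
from conftest import make_annotation


def exact_tail(k, n, K, N):
    """Exact rational upper-tail probability by direct enumeration."""
    num = sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    )
    return Fraction(num, comb(N, n))


class TestHypergeomTail:
    def test_certain_event(self):
        assert hypergeom_tail(0, 3, 4, 10) == 1.0

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            hypergeom_tail(4, 3, 4, 10)

    def test_enumerated_example(self):
        # N=10, K=4, n=3: P[X >= 2] = 40/120
        assert hypergeom_tail(2, 3, 4, 10) == pytest.approx(40 / 120, rel=1e-12)

    def test_matches_exact_enumeration_small(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        expected = float(exact_tail(k, n, K, N))
                        assert hypergeom_tail(k, n, K, N) == pytest.approx(
                            expected, rel=1e-10
                        ), (k, n, K, N)

    def test_monotone_in_k_and_pmf_sums_to_one(self):
        N, K, n = 25, 11, 9
        tails = [hypergeom_tail(k, n, K, N) for k in range(min(n, K) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        assert tails[0] == 1.0
        pmf_sum = sum(
            tails[k] - (tails[k + 1] if k + 1 < len(tails) else 0.0)
            for k in range(len(tails))
        )
        assert pmf_sum == pytest.approx(1.0, abs=1e-12)

    def test_extreme_tail_stays_finite(self):
        logp = log_hypergeom_tail(100, 100, 400, 20_000)
        assert math.isfinite(logp) and logp < -100

    def test_precondition_checks(self):
        with pytest.raises(ValueError):
            hypergeom_tail(0, 11, 4, 10)  # n > N
        with pytest.raises(ValueError):
            hypergeom_tail(-1, 3, 4, 10)


class TestOverlapEnrichment:
    def test_query_equals_universe(self):
        genes = {f"g{i}" for i in range(20)}
        res = overlap_enrichment(genes, genes, genes)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_disjoint_sets(self):
        universe = {f"g{i}" for i in range(100)}
        res = overlap_enrichment(
            {f"g{i}" for i in range(10)}, {f"g{i}" for i in range(50, 60)}, universe
        )
        assert res.k == 0 and res.p == pytest.approx(1.0)

    def test_fold_and_log_space_tail(self):
        universe = {f"g{i}" for i in range(1000)}
        reference = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(80, 130)}  # k=20 of n=50
        res = overlap_enrichment(query, reference, universe)
        assert (res.k, res.n, res.K, res.N) == (20, 50, 100, 1000)
        assert res.fold == pytest.approx((20 / 50) / (100 / 1000))
        # same configuration at reduced scale against exact enumeration
        small = overlap_enrichment(
            {f"g{i}" for i in range(4, 9)}, {f"g{i}" for i in range(10)},
            {f"g{i}" for i in range(25)},
        )
        assert small.p == pytest.approx(
            float(exact_tail(small.k, small.n, small.K, small.N)), rel=1e-10
        )

    def test_genes_outside_universe_dropped_with_warning(self):
        universe = {"a", "b", "c", "d"}
        with pytest.warns(UserWarning, match="outside"):
            res = overlap_enrichment({"a", "zzz"}, {"a", "b"}, universe)
        assert (res.k, res.n) == (1, 1)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment({"a"}, {"a"}, set())

    def test_ease_is_more_conservative(self):
        universe = {f"g{i}" for i in range(100)}
        q = {f"g{i}" for i in range(10)}
        r = {f"g{i}" for i in range(5, 25)}
        plain = overlap_enrichment(q, r, universe)
        ease = overlap_enrichment(q, r, universe, ease=True)
        assert ease.p >= plain.p


def two_chrom_annotation(n_per_chrom=50):
    genes = []
    for chrom in ("I", "II"):
        for i in range(n_per_chrom):
            start = 1000 * (i + 1)
            genes.append((f"{chrom}_g{i}", chrom, "+", start, start + 500))
    return make_annotation(genes, {"I": 200_000, "II": 200_000})


class TestChromosomeDistribution:
    def test_proportional_targets_give_ratio_one(self):
        ann = two_chrom_annotation()
        targets = {f"I_g{i}" for i in range(5)} | {f"II_g{i}" for i in range(5)}
        res = chromosome_distribution(targets, ann)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert all(r == pytest.approx(1.0) for r in res.table["ratio"])

    def test_worked_two_chromosome_example(self):
        # genes 50/50, targets 8 vs 2: E=(5,5), chi2 = 9/5 + 9/5 = 3.6, df 1
        ann = two_chrom_annotation()
        targets = {f"I_g{i}" for i in range(8)} | {f"II_g{i}" for i in range(2)}
        res = chromosome_distribution(targets, ann)
        assert res.chi2 == pytest.approx(3.6)
        assert res.df == 1
        assert res.p == pytest.approx(float(chi2_dist.sf(3.6, 1)), rel=1e-10)
        assert res.p == pytest.approx(0.0578, abs=5e-5)

    def test_expected_weighted_ratios_average_to_one(self):
        ann = two_chrom_annotation()
        targets = {f"I_g{i}" for i in range(8)} | {f"II_g{i}" for i in range(2)}
        res = chromosome_distribution(targets, ann)
        weighted = (res.table["ratio"] * res.table["expected"]).sum()
        assert weighted / res.table["expected"].sum() == pytest.approx(1.0)

    def test_unknown_target_rejected(self):
        ann = two_chrom_annotation()
        with pytest.raises(KeyError):
            chromosome_distribution({"nope"}, ann)


class TestGermlineFraction:
    def test_all_targets_germline(self):
        universe = {f"g{i}" for i in range(100)}
        germ = {f"g{i}" for i in range(20)}
        frac, res = germline_fraction({"g0", "g1"}, germ, universe)
        assert frac == 1.0

    def test_disjoint_targets(self):
        universe = {f"g{i}" for i in range(100)}
        germ = {f"g{i}" for i in range(20)}
        frac, res = germline_fraction({"g50", "g51"}, germ, universe)
        assert frac == 0.0 and res.p == pytest.approx(1.0)

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            germline_fraction(set(), {"a"}, {"a", "b"})

    def test_chisquare_agrees_with_expected_arithmetic(self):
        universe = {f"g{i}" for i in range(200)}
        germ = {f"g{i}" for i in range(40)}
        targets = {f"g{i}" for i in range(20, 50)}
        chi2, p = germline_chisquare(targets, germ, universe)
        a = len(targets & germ)
        table = np.array(
            [
                [a, len(targets) - a],
                [len(germ) - a, 200 - len(targets) - len(germ) + a],
            ],
            dtype=float,
        )
        expected = table.sum(1, keepdims=True) @ table.sum(0, keepdims=True) / 200
        assert chi2 == pytest.approx(float(((table - expected) ** 2 / expected).sum()))
        assert 0 < p < 1


class TestTermEnrichment:
    def universe(self):
        return {f"g{i}" for i in range(1000)}

    def test_perfect_term_ranks_first(self):
        universe = self.universe()
        targets = {f"g{i}" for i in range(20)}
        gene_terms = {f"g{i}": {"broad"} for i in range(500)}
        for g in targets:
            gene_terms.setdefault(g, set()).add("perfect")
        rows = term_enrichment(targets, gene_terms, universe)
        assert rows and rows[0].term == "perfect"

    def test_low_fold_filtered_regardless_of_p(self):
        universe = self.universe()
        targets = {f"g{i}" for i in range(400)}
        # term hits 60% of targets but covers 40% of the universe: fold 1.5
        term_genes = {f"g{i}" for i in range(240)} | {
            f"g{i}" for i in range(400, 560)
        }
        gene_terms = {g: {"weak"} for g in term_genes}
        rows = term_enrichment(targets, gene_terms, universe)
        assert rows == []

    def test_top_ten_truncation_and_ordering(self):
        universe = self.universe()
        targets = {f"g{i}" for i in range(40)}
        gene_terms = {}
        for t in range(12):
            for i in range(5 + t):  # nested terms, increasingly large overlap
                gene_terms.setdefault(f"g{i}", set()).add(f"term_{t:02d}")
        rows = term_enrichment(targets, gene_terms, universe)
        assert len(rows) == 10
        ps = [r.p for r in rows]
        assert ps == sorted(ps)

    def test_deterministic_tie_break_by_term_id(self):
        universe = self.universe()
        targets = {f"g{i}" for i in range(10)}
        gene_terms = {f"g{i}": {"b_term", "a_term"} for i in range(10)}
        rows = term_enrichment(targets, gene_terms, universe)
        assert [r.term for r in rows] == ["a_term", "b_term"]
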