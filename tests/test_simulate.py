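"""The synthetic-data generator: determinism, planted structure, and the
statistical behavior of each noise model."""

import math

import numpy as np
import pytest

from tissuechip.classification import classify, default_category_definitions
from tissuechip.concordance import pearson, replicate_correlation
from tissuechip.model import GenomicInterval, IntervalIndex, Peak, PeakSet
from tissuechip.properties import width_stats
from tissuechip.simulate import (
    SimConfig,
    make_regulated_list,
    score_recovery,
    simulate_binding,
    simulate_genome,
    simulate_reads,
    simulate_regulated_lists,
    write_dataset,
)
from conftest import SMALL_CONFIG


class TestSimulateGenome:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(d1, SMALL_CONFIG)
        write_dataset(d2, SMALL_CONFIG)
        for name in (
            "genes.gff3",
            "germline_genes.txt",
            "peaks/EFL-1@germline.narrowPeak",
            "truth_sites.tsv",
            "reads_rep1.bed",
            "terms.gmt",
        ):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_zero_germline_fraction(self):
        cfg = SMALL_CONFIG.with_overrides(germline_fraction=0.0)
        _, germline = simulate_genome(cfg)
        assert germline == []

    def test_germline_count_binomial(self):
        cfg = SimConfig(seed=21, genes_per_chrom=2000)  # 12,000 genes
        ann, germline = simulate_genome(cfg)
        n, f = len(ann), cfg.germline_fraction
        se = math.sqrt(n * f * (1 - f))
        assert abs(len(germline) - n * f) < 3 * se

    def test_x_downweighting_preserves_overall_fraction(self):
        cfg = SimConfig(seed=22, genes_per_chrom=2000)
        ann, germline = simulate_genome(cfg)
        germ = set(germline)
        x_genes = [g for g in ann.genes.values() if ann.is_x(g.chrom)]
        x_frac = sum(1 for g in x_genes if g.gene_id in germ) / len(x_genes)
        assert x_frac < cfg.germline_fraction / 2  # X clearly depleted

    def test_gene_spans_never_overlap(self):
        ann, _ = simulate_genome(SMALL_CONFIG)
        by_chrom = {}
        for g in ann.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g.span)
        for spans in by_chrom.values():
            spans.sort(key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start

    def test_infeasible_density_rejected(self):
        cfg = SimConfig(
            seed=0,
            chromosomes=(("I", 100_000, False),),
            genes_per_chrom=500,
        )
        with pytest.raises(ValueError, match="longer chromosomes"):
            simulate_genome(cfg)


class TestSimulateBinding:
    def test_planted_counts_and_exclusion(self, small_sim):
        truth = small_sim["truth"]
        peaksets = small_sim["peaksets"]
        assert truth.category_counts() == dict(SMALL_CONFIG.sites_per_category)
        # no planted site interval overlaps any peak of its category's
        # exclude datasets
        defs = {d.name: d for d in default_category_definitions()}
        indexes = {k: IntervalIndex(ps.intervals) for k, ps in peaksets.items()}
        for site in truth.sites:
            for key in defs[site.category].exclude:
                assert not indexes[key].overlaps(site.anchor), (site.site_id, key)

    def test_zero_sites_everywhere(self):
        cfg = SMALL_CONFIG.with_overrides(
            sites_per_category={k: 0 for k in SMALL_CONFIG.sites_per_category},
        )
        ann, germ = simulate_genome(cfg)
        peaksets, truth = simulate_binding(cfg, ann, germ)
        assert truth.sites == []
        assert all(len(ps) == 0 for ps in peaksets.values())

    def test_planted_tier_distances_verified(self, small_sim):
        truth = small_sim["truth"]
        ann = small_sim["annotation"]
        cfg = small_sim["config"]
        from tissuechip.targets import site_tss_distance

        for site in truth.sites:
            if site.tier == "unassigned":
                dmin = min(
                    site_tss_distance(site.anchor, g)
                    for g in ann.genes.values()
                    if g.chrom == site.anchor.chrom
                )
                assert dmin > cfg.low_dist
            else:
                d = site_tss_distance(site.anchor, ann.genes[site.target_gene])
                assert d == site.distance
                if site.tier == "high":
                    assert d < cfg.high_dist
                else:
                    assert cfg.high_dist <= d <= cfg.low_dist

    def test_dropout_reduces_recovery_continuously(self):
        cfg = SMALL_CONFIG.with_overrides(seed=31, dropout=0.04)
        ann, germ = simulate_genome(cfg)
        peaksets, truth = simulate_binding(cfg, ann, germ)
        cl = classify(peaksets, default_category_definitions(peaksets))
        sc = score_recovery(truth, cl)
        # off-diagonal mass appears only as 'none' (dropped anchors or
        # dropped include peaks), never as cross-category flips
        conf = sc["confusion"]
        for cat in conf.index:
            others = [c for c in conf.columns if c not in (cat, "none")]
            assert conf.loc[cat, others].sum() == 0
            assert sc["recovery"][cat] > (1 - 0.04) ** 3 - 0.15

    def test_spurious_peaks_labelled(self):
        cfg = SMALL_CONFIG.with_overrides(seed=32, spurious_rate=20.0)
        ann, germ = simulate_genome(cfg)
        peaksets, truth = simulate_binding(cfg, ann, germ)
        n_spur = sum(len(v) for v in truth.spurious_peak_names.values())
        assert n_spur > 0
        for key, names in truth.spurious_peak_names.items():
            in_set = {p.name for p in peaksets[key]}
            assert names <= in_set


class TestSimulateReads:
    def test_same_seed_identical_tracks(self, small_sim):
        cfg = small_sim["config"]
        ps = small_sim["peaksets"]["EFL-1@germline"]
        a1, b1 = simulate_reads(ps, cfg, label="x")
        a2, b2 = simulate_reads(ps, cfg, label="x")
        assert a1.reads == a2.reads and b1.reads == b2.reads

    def test_independent_replicates_uncorrelated(self):
        # phi = 0: independent Poisson replicates over 2,000 windows
        cfg = SimConfig(seed=33, phi=0.0, read_depth_mu=30.0)
        ps = PeakSet("F", "t", [Peak(interval=GenomicInterval("I", 0, 200_000))])
        a, b = simulate_reads(ps, cfg, label="indep")
        r = replicate_correlation(ps, a, b, cfg.window)
        assert abs(r) < 0.1

    def test_overdispersed_replicates_match_closed_form(self):
        # phi*mu = 10 -> r = 10/11
        cfg = SimConfig(seed=34, phi=0.1, read_depth_mu=100.0)
        ps = PeakSet("F", "t", [Peak(interval=GenomicInterval("I", 0, 300_000))])
        a, b = simulate_reads(ps, cfg, label="od")
        r = replicate_correlation(ps, a, b, cfg.window)
        target = 10 / 11
        se = (1 - target**2) / math.sqrt(3000)
        assert abs(r - target) < 3 * se


class TestRegulatedLists:
    def test_planted_overlap_exact(self, small_sim):
        truth = small_sim["truth"]
        ann = small_sim["annotation"]
        lists = simulate_regulated_lists(truth, ann, small_sim["config"])
        reg = set(lists["gonad_down"])
        targets = truth.target_genes("germline_specific")
        assert len(reg) == 20
        assert len(reg & targets) == 8

    def test_full_overlap_no_background(self, small_sim):
        rng = np.random.default_rng(0)
        truth, ann = small_sim["truth"], small_sim["annotation"]
        lst = make_regulated_list(truth, ann, "soma_specific", 10, 10, rng)
        assert set(lst) <= truth.target_genes("soma_specific")

    def test_excessive_overlap_rejected(self, small_sim):
        rng = np.random.default_rng(0)
        truth, ann = small_sim["truth"], small_sim["annotation"]
        with pytest.raises(ValueError, match="exceeds"):
            make_regulated_list(truth, ann, "soma_specific", 10_000, 9_999, rng)

    def test_background_only_near_null_fold(self, small_sim):
        from tissuechip.enrichment import overlap_enrichment

        rng = np.random.default_rng(1)
        truth, ann = small_sim["truth"], small_sim["annotation"]
        universe = set(ann.genes)
        targets = truth.target_genes("germline_specific")
        lst = make_regulated_list(truth, ann, "germline_specific", 300, 0, rng)
        res = overlap_enrichment(targets, set(lst), universe)
        assert res.k == 0 or res.fold < 3  # no planted signal


class TestWidthPlanting:
    def test_intestine_twice_as_wide(self):
        cfg = SimConfig(
            seed=41,
            sites_per_category={
                "germline_specific": 150,
                "soma_specific": 150,
                "intestine_specific": 150,
                "broadly_bound": 150,
            },
            regulated_lists=(),
        )
        ann, germ = simulate_genome(cfg)
        peaksets, truth = simulate_binding(cfg, ann, germ)
        cl = classify(peaksets, default_category_definitions(peaksets))
        stats = {w.category: w.mean for w in width_stats(cl)}
        others = np.mean(
            [stats["germline_specific"], stats["soma_specific"], stats["broadly_bound"]]
        )
        assert 1.7 < stats["intestine_specific"] / others < 2.3
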