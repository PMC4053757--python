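"""Category classification: binding predicates, priority resolution,
default tissue-category definitions."""

import numpy as np
import pytest

from tissuechip.classification import (
    CategoryDefinition,
    classify,
    default_category_definitions,
    site_support,
)
from tissuechip.model import GenomicInterval, Peak, PeakSet, overlap_bp


def iv(start, end, chrom="I"):
    return GenomicInterval(chrom, start, end)


def peakset(intervals, key="A@t"):
    factor, tissue = key.split("@")
    return PeakSet(factor, tissue, [Peak(interval=v) for v in intervals])


class TestCategoryDefinition:
    def test_anchor_must_be_included(self):
        with pytest.raises(ValueError, match="anchor"):
            CategoryDefinition("c", anchor="A@t", include=("B@t",))

    def test_include_exclude_disjoint(self):
        with pytest.raises(ValueError, match="both"):
            CategoryDefinition("c", "A@t", include=("A@t", "B@t"), exclude=("B@t",))


class TestSiteSupport:
    def test_overlap_and_touch(self):
        sets = {"K@t": peakset([iv(150, 400)], "K@t"), "L@t": peakset([iv(200, 400)], "L@t")}
        support = site_support(iv(100, 200), sets)
        assert support == {"K@t": True, "L@t": False}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        keys = [f"K{j}@t" for j in range(5)]
        sets = {
            k: peakset(
                [
                    iv(int(s), int(s) + int(w))
                    for s, w in zip(rng.integers(0, 20_000, 30), rng.integers(10, 500, 30))
                ],
                k,
            )
            for k in keys
        }
        for _ in range(200):
            start = int(rng.integers(0, 20_000))
            site = iv(start, start + int(rng.integers(1, 400)))
            got = site_support(site, sets, min_overlap=1)
            brute = {
                k: any(overlap_bp(site, p.interval) >= 1 for p in sets[k])
                for k in keys
            }
            assert got == brute


def toy_universe():
    """8 anchor peaks x 3 auxiliary datasets with hand-built overlaps."""
    anchors = [iv(1000 * i, 1000 * i + 100) for i in range(8)]
    # B overlaps anchors 0-3; C overlaps anchors 2-5; D overlaps 0, 6
    sets = {
        "A@t": peakset(anchors, "A@t"),
        "B@t": peakset([iv(1000 * i + 50, 1000 * i + 150) for i in range(4)], "B@t"),
        "C@t": peakset([iv(1000 * i + 50, 1000 * i + 150) for i in range(2, 6)], "C@t"),
        "D@t": peakset([iv(50, 90), iv(6050, 6090)], "D@t"),
    }
    return anchors, sets


class TestClassify:
    def test_truth_table_on_toy_universe(self):
        anchors, sets = toy_universe()
        definitions = [
            CategoryDefinition("b_not_c", "A@t", include=("A@t", "B@t"), exclude=("C@t",)),
            CategoryDefinition("c_not_d", "A@t", include=("A@t", "C@t"), exclude=("D@t",)),
            CategoryDefinition("d_only", "A@t", include=("A@t", "D@t")),
        ]
        result = classify(sets, definitions)
        # exhaustive hand evaluation: B hits {0,1,2,3}, C hits {2,3,4,5}, D hits {0,6}
        assert [p.interval for p in result.sites["b_not_c"]] == [anchors[0], anchors[1]]
        assert [p.interval for p in result.sites["c_not_d"]] == [
            anchors[2], anchors[3], anchors[4], anchors[5],
        ]
        # anchor 0 matched b_not_c (priority) and d_only; 6 is d_only alone
        assert [p.interval for p in result.sites["d_only"]] == [anchors[6]]
        assert len(result.conflicts) == 1
        assert result.conflicts[0].winner == "b_not_c"
        assert result.conflicts[0].losers == ("d_only",)
        # anchor 7 satisfies nothing
        assert [p.interval for p in result.unclassified["A@t"]] == [anchors[7]]

    def test_vacuous_definition_returns_anchor_set(self):
        anchors, sets = toy_universe()
        result = classify(sets, [CategoryDefinition("all", "A@t", include=("A@t",))])
        assert [p.interval for p in result.sites["all"]] == anchors

    def test_empty_anchor_warns_not_errors(self):
        sets = {"A@t": peakset([], "A@t")}
        with pytest.warns(UserWarning, match="empty"):
            result = classify(sets, [CategoryDefinition("c", "A@t", include=("A@t",))])
        assert result.sites["c"] == []

    def test_categories_always_disjoint(self):
        rng = np.random.default_rng(6)
        keys = [f"K{j}@t" for j in range(4)]
        for _ in range(20):
            sets = {
                k: peakset(
                    [
                        iv(int(s), int(s) + int(w))
                        for s, w in zip(
                            rng.integers(0, 5000, 15), rng.integers(10, 300, 15)
                        )
                    ],
                    k,
                )
                for k in keys
            }
            definitions = [
                CategoryDefinition("c1", keys[0], include=(keys[0], keys[1])),
                CategoryDefinition("c2", keys[0], include=(keys[0],), exclude=(keys[2],)),
                CategoryDefinition("c3", keys[0], include=(keys[0],)),
            ]
            result = classify(sets, definitions)
            seen = set()
            for cat, peaks in result.sites.items():
                for p in peaks:
                    assert p.interval not in seen
                    seen.add(p.interval)

    def test_removing_exclusion_grows_category(self):
        anchors, sets = toy_universe()
        with_excl = classify(
            sets, [CategoryDefinition("c", "A@t", include=("A@t", "B@t"), exclude=("C@t",))]
        )
        without = classify(
            sets, [CategoryDefinition("c", "A@t", include=("A@t", "B@t"))]
        )
        a = {p.interval for p in with_excl.sites["c"]}
        b = {p.interval for p in without.sites["c"]}
        assert a <= b

    def test_invariant_to_peak_order(self):
        anchors, sets = toy_universe()
        shuffled = {
            k: PeakSet(ps.factor, ps.tissue, list(reversed(ps.peaks)))
            for k, ps in sets.items()
        }
        defs = [CategoryDefinition("c", "A@t", include=("A@t", "B@t"), exclude=("C@t",))]
        assert (
            [p.interval for p in classify(sets, defs).sites["c"]]
            == [p.interval for p in classify(shuffled, defs).sites["c"]]
        )


class TestDefaultDefinitions:
    def test_priority_order_and_anchors(self):
        defs = default_category_definitions()
        assert [d.name for d in defs] == [
            "germline_specific",
            "soma_specific",
            "intestine_specific",
            "broadly_bound",
        ]
        for d in defs:
            assert d.anchor in d.include
        by_name = {d.name: d for d in defs}
        assert by_name["germline_specific"].anchor == "EFL-1@germline"
        assert by_name["germline_specific"].exclude == ("DPL-1@soma",)
        assert set(by_name["soma_specific"].include) == {
            "EFL-1@soma", "DPL-1@soma", "LIN-35@soma",
        }
        assert set(by_name["soma_specific"].exclude) == {
            "EFL-1@germline", "HPL-2@intestine",
        }
        assert by_name["intestine_specific"].anchor == "LIN-35@intestine"
        assert by_name["broadly_bound"].exclude == ()

    def test_missing_dataset_named_in_error(self):
        with pytest.raises(KeyError, match="HPL-2@intestine"):
            default_category_definitions({"EFL-1@germline"})
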