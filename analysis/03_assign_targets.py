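#!/usr/bin/env python
"""Assign classified sites to candidate target genes by TSS distance.

For every category: number of sites, high/low-tier assignments, unique
target genes, and the fraction of sites with no gene within 2,000 bp.
More sites than genes or vice versa is expected — a site may regulate
several genes and several sites may share one gene.

Writes results/analysis/03_targets.tsv.
"""

from pathlib import Path

import pandas as pd

from tissuechip.classification import classify, default_category_definitions
from tissuechip.model import PipelineParams
from tissuechip.properties import unassignable_fraction
from tissuechip.simulate import SimConfig, simulate_binding, simulate_genome
from tissuechip.targets import assign_targets, target_gene_set

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260927


def main() -> None:
    config = SimConfig(seed=SEED)
    annotation, germline = simulate_genome(config)
    peaksets, truth = simulate_binding(config, annotation, germline)
    classified = classify(peaksets, default_category_definitions(peaksets))
    params = PipelineParams()

    rows = []
    for cat in classified.sites:
        sites = classified.intervals(cat)
        table = assign_targets(sites, annotation, params, category=cat)
        rows.append(
            {
                "category": cat,
                "n_sites": len(sites),
                "assignments_high": sum(1 for a in table.assignments if a.tier == "high"),
                "assignments_low": sum(1 for a in table.assignments if a.tier == "low"),
                "target_genes_high": len(target_gene_set(table, tiers=("high",))),
                "target_genes_all": len(target_gene_set(table)),
                "unassignable_fraction": round(unassignable_fraction(table), 4),
            }
        )
    out = pd.DataFrame(rows)
    dest = ROOT / "results" / "analysis"
    dest.mkdir(parents=True, exist_ok=True)
    out.to_csv(dest / "03_targets.tsv", sep="\t", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
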