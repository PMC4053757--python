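"""Shared fixtures: hand-built toy annotations and seeded synthetic studies."""

from __future__ import annotations

import pytest

from tissuechip.model import GeneModel, GenomeAnnotation, GenomicInterval
from tissuechip.simulate import (
    SimConfig,
    simulate_binding,
    simulate_genome,
)

# scaled-down study used by most integration tests
SMALL_CONFIG = SimConfig(
    seed=11,
    sites_per_category={
        "germline_specific": 40,
        "soma_specific": 30,
        "intestine_specific": 50,
        "broadly_bound": 80,
    },
    genes_per_chrom=400,
    regulated_lists=(("gonad_down", "germline_specific", 20, 8),),
)


def make_annotation(genes, lengths, x_chromosomes=()):
    """Build an annotation from (gene_id, chrom, strand, start, end) tuples
    (0-based half-open)."""
    models = [
        GeneModel(gid, chrom, strand, GenomicInterval(chrom, start, end))
        for gid, chrom, strand, start, end in genes
    ]
    return GenomeAnnotation(lengths, models, x_chromosomes=x_chromosomes)


@pytest.fixture(scope="session")
def small_sim():
    annotation, germline = simulate_genome(SMALL_CONFIG)
    peaksets, truth = simulate_binding(SMALL_CONFIG, annotation, germline)
    return {
        "config": SMALL_CONFIG,
        "annotation": annotation,
        "germline": germline,
        "peaksets": peaksets,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    from tissuechip.simulate import write_dataset

    outdir = tmp_path_factory.mktemp("simdata")
    write_dataset(outdir, SMALL_CONFIG)
    return outdir


@pytest.fixture(scope="session")
def default_sim():
    """Full-scale zero-noise study with the default planted structure."""
    config = SimConfig(seed=7)
    annotation, germline = simulate_genome(config)
    peaksets, truth = simulate_binding(config, annotation, germline)
    return {
        "config": config,
        "annotation": annotation,
        "germline": germline,
        "peaksets": peaksets,
        "truth": truth,
    }
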