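import logging

import pytest

from mhcrep import calling, seqio, simlib

logging.getLogger("mhcrep").setLevel(logging.ERROR)


def reads_from_libraries(libraries):
    """Flatten simulator output into CloneRead objects."""
    return [
        seqio.CloneRead(h.split("|")[0], k[0], k[1], k[2], s)
        for k, recs in sorted(libraries.items())
        for h, s in recs
    ]


@pytest.fixture(scope="session")
def clean_library():
    """Small no-noise library: every clone is an exact true-allele copy."""
    cfg = simlib.SimConfig(
        n_loci=4,
        alleles_per_locus=3,
        n_individuals=4,
        error_rate=0.0,
        chimera_rate=0.0,
        depth_per_replicate=12,
        locus_retention=1.0,
        n_cdna_individuals=2,
        seed=7,
    )
    alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
    libraries, truth = simlib.simulate_clone_library(alleles, genotypes, expression, cfg)
    return cfg, libraries, truth


@pytest.fixture(scope="session")
def chimeric_library():
    """Error-free library with a high chimera rate."""
    cfg = simlib.SimConfig(
        n_loci=3,
        alleles_per_locus=3,
        n_individuals=3,
        error_rate=0.0,
        chimera_rate=0.3,
        depth_per_replicate=20,
        locus_retention=1.0,
        seed=3,
    )
    alleles, genotypes, expression = simlib.simulate_repertoire(cfg)
    libraries, truth = simlib.simulate_clone_library(alleles, genotypes, expression, cfg)
    return cfg, libraries, truth


@pytest.fixture(scope="session")
def gene_model():
    return simlib.default_gene_model(0)


def call_pipeline(libraries):
    """simulate -> collapse -> chimera filter -> confirm, returning all
    intermediate layers (the common test path)."""
    reads = reads_from_libraries(libraries)
    variants = calling.collapse_identical(reads)
    clean, chimera_calls = calling.detect_chimeras(variants)
    alleles = calling.confirm_alleles(clean)
    return reads, variants, clean, chimera_calls, alleles
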