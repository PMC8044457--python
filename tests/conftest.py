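"""Shared fixtures: small deterministic simulations reused across tests."""

from __future__ import annotations

import pytest

from methylgen.dmr import enumerate_comparisons, test_all_regions
from methylgen.simulate import (PlannedDMR, SimulationConfig,
                                generate_annotations, generate_genome,
                                generate_methylomes, write_dataset)
from methylgen.types import DMRParams


@pytest.fixture(scope="session")
def recovery_sim():
    """Default-scale simulation with the default planted-DMR plan (seed 1)."""
    config = SimulationConfig(seed=1)
    genome = generate_genome(config)
    genes, tes = generate_annotations(config, genome)
    am, manifest, condition_levels = generate_methylomes(config, genome, tes)
    return {"config": config, "genome": genome, "genes": genes, "tes": tes,
            "am": am, "manifest": manifest,
            "condition_levels": condition_levels}


@pytest.fixture(scope="session")
def recovery_tested(recovery_sim):
    """Tested-region table for every comparison on the recovery simulation."""
    config = recovery_sim["config"]
    comparisons = enumerate_comparisons(config.generations, config.doses)
    tested = test_all_regions(recovery_sim["am"], comparisons,
                              config.chrom_lengths, DMRParams())
    return tested, comparisons


def small_config(seed: int = 3, **overrides) -> SimulationConfig:
    defaults = dict(
        seed=seed, n_chromosomes=1, chrom_length=24_000, n_genes=8, n_tes=6,
        dmr_plan=(PlannedDMR("intragenerational", "S2g0_vs_S2g30", "CG",
                             "hyper", 0.30, 2, 1000),
                  PlannedDMR("intragenerational", "S2g0_vs_S2g30", "CG",
                             "hypo", 0.30, 2, 1000)))
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """Tiny single-chromosome simulation for fast structural tests."""
    config = small_config()
    genome = generate_genome(config)
    genes, tes = generate_annotations(config, genome)
    am, manifest, condition_levels = generate_methylomes(config, genome, tes)
    return {"config": config, "genome": genome, "genes": genes, "tes": tes,
            "am": am, "manifest": manifest,
            "condition_levels": condition_levels}


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """The same tiny simulation written to disk as a loadable dataset."""
    outdir = tmp_path_factory.mktemp("dataset")
    config = small_config()
    write_dataset(config, outdir)
    return config, outdir
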