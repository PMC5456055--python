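"""Shared fixtures: one simulated 11-taxon data set, partitioned, with
per-region divergence statistics and the whole-genome concatenation, built
once per session and reused by the unit and acceptance tests."""

import pytest

from plastome_compare import (align_region, detect_ir, divergence_stats,
                              extract_regions)
from plastome_compare.simulate import SimConfig, simulate

SIM_SEED = 1


@pytest.fixture(scope="session")
def sim_result():
    return simulate(SimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def partitions(sim_result):
    return [detect_ir(r) for r in sim_result.records]


@pytest.fixture(scope="session")
def region_set(partitions):
    return extract_regions(partitions)


@pytest.fixture(scope="session")
def region_stats(region_set):
    stats = []
    for name, region in region_set.regions.items():
        aln = align_region(region.seqs, name=name)
        stats.append(divergence_stats(aln, category=region.category))
    return stats


@pytest.fixture(scope="session")
def concat_alignment(partitions):
    stripped = {
        p.record.id: p.record.seq[: p.genome_length - p.ir_length]
        for p in partitions
    }
    return align_region(stripped, name="concatenation")
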