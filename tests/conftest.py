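import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bnaepi.simulate import (
    PlantedCleavage,
    PlantedDMR,
    PlantedMiRNA,
    SimulationConfig,
    simulate_genome,
    simulate_methylome,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_config():
    """Small study with one planted DMR per direction and miRNA effects."""
    return SimulationConfig(
        seed=42,
        chromosome_length=20_000,
        n_genes=8,
        dmr_plan=[
            PlantedDMR("A01", 5_001, 5_450, "CG", +0.30),
            PlantedDMR("C01", 8_001, 8_400, "CHG", -0.15),
        ],
        mirna_plan=[
            PlantedMiRNA("Bna-synthetic-miR1", 21, +2.0, 200),
            PlantedMiRNA("Bna-synthetic-miR2", 24, -2.0, 200),
        ]
        + [PlantedMiRNA(f"Bna-synthetic-miR{i}", 21, 0.0, 100)
           for i in range(3, 31)],
        cleavage_plan=[
            PlantedCleavage("Bna-synthetic-miR1", "SYNT0001", 100,
                            n_wobbles=1, n_mismatches=0, peak_reads=50)
        ],
    )


@pytest.fixture(scope="session")
def demo_genome(demo_config):
    return simulate_genome(demo_config)


@pytest.fixture(scope="session")
def demo_reports(demo_config, demo_genome):
    genome, _ = demo_genome
    return (
        simulate_methylome(genome, demo_config, "0h"),
        simulate_methylome(genome, demo_config, "72h"),
    )


def uniform_report(genome, mc=15, umc=15):
    """CX report pair helper: every cytosine at the same level."""
    from bnaepi.methylation import call_cytosine_contexts

    sites = call_cytosine_contexts(genome)
    rep = sites.copy()
    rep.insert(3, "count_methylated", mc)
    rep.insert(4, "count_unmethylated", umc)
    return rep
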