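import numpy as np
import pandas as pd
import pytest

from quantchip import TruthConfig, generate_genome, simulate_chip_counts
from quantchip.relacs import SampleCountTable


@pytest.fixture(scope="session")
def small_config():
    return TruthConfig(
        seed=11,
        n_genes=60,
        n_enhancers=30,
        depth=80_000,
        chromosome_length=3_000_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_config, small_genome):
    return simulate_chip_counts(small_genome, small_config)


@pytest.fixture(scope="session")
def tiny_experiment():
    """Read-scale fixture: few samples, shallow depth, for FASTQ round trips."""
    cfg = TruthConfig(
        seed=13,
        n_genes=25,
        n_enhancers=10,
        depth=4000,
        chromosome_length=1_500_000,
        marks=("H3K4me3", "H3K79me2"),
    )
    genome = generate_genome(cfg)
    return simulate_chip_counts(genome, cfg)


def make_table(counts, *, sample_id="s", role="chip", mark="H3K79me2",
               condition="A", replicate=1, total=None):
    """Hand-built SampleCountTable for forced-arithmetic tests."""
    series = pd.Series(np.asarray(counts), index=pd.RangeIndex(len(counts), name="region_id"))
    return SampleCountTable(
        sample_id=sample_id,
        role=role,
        mark=mark,
        condition=condition,
        replicate=replicate,
        genome_total=int(series.sum()) if total is None else int(total),
        counts=series,
    )
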