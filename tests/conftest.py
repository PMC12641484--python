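import numpy as np
import pytest

from chronoscan.simdata import (
    PlantedRegion,
    SimConfig,
    simulate_pool_counts,
    simulate_site_frequencies,
)
from chronoscan.syncio import SyncRecord


def make_record(scaffold="scaf1", position=100, ref="A", pools=((10, 2, 0, 0, 0, 0), (5, 7, 0, 0, 0, 0))):
    return SyncRecord(scaffold, position, ref, np.array(pools))


@pytest.fixture
def record():
    """Two pools: pool1 A=10 T=2, pool2 A=5 T=7."""
    return make_record()


@pytest.fixture(scope="session")
def planted_config():
    """A small two-pool study with one strongly differentiated 5-kb block
    inside a 100-kb scaffold."""
    return SimConfig(
        n_scaffolds=1,
        scaffold_length_bp=100_000,
        depth_mean=30.0,
        planted_regions=(PlantedRegion("scaffold_1", 40_000, 45_000, 0.6),),
        n_genes=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def planted_records(planted_config):
    truth = simulate_site_frequencies(planted_config)
    records = simulate_pool_counts(truth, planted_config)
    return truth, records
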