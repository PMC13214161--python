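import numpy as np
import pytest

from tsponet.atlas import reduced_atlas
from tsponet.pipeline import edge_table
from tsponet.simulate import BatchSpec, CohortBlock, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def atlas20():
    return reduced_atlas()


@pytest.fixture(scope="session")
def noiseless_hc_cohort():
    """Six noise-free healthy controls on the 20-region atlas."""
    cfg = SimConfig(batches=(BatchSpec("SITE1", noise_level=0.0),),
                    cohort=(CohortBlock("SITE1", "HC", 6),), seed=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_hc_edges(noiseless_hc_cohort):
    c = noiseless_hc_cohort
    edges, cov = edge_table(c.scans, c.records)
    return edges, cov, c


@pytest.fixture
def rng():
    return np.random.default_rng(0)
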