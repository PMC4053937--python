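import numpy as np
import pytest
from hypothesis import settings

from paremir import mapping, normalization
from paremir.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    """One seeded synthetic study shared by the pipeline-level tests."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def dataset_hits(dataset):
    hits = mapping.map_tags(dataset.genome, dataset.smallrna.tags, 20)
    normalization.attach_genome_matched_totals(dataset.smallrna, hits)
    return hits


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
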