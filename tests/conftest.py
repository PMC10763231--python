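import pytest
from hypothesis import HealthCheck, settings

import gutgroups as gg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    """One synthetic study (3 diets x 2 weeks x 6 replicates, seed 0)."""
    return gg.simulate_dataset(gg.SimulationParams(seed=0))


@pytest.fixture(scope="session")
def phylum_relative(dataset):
    raw = gg.aggregate_by_category(dataset.abundance, dataset.annotations, "phylum")
    return gg.to_relative(raw)


@pytest.fixture(scope="session")
def genus_relative(dataset):
    raw = gg.aggregate_by_category(dataset.abundance, dataset.annotations, "genus")
    return gg.to_relative(raw)
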