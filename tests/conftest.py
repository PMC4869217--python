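import pytest

from venuescope import fixtures, synthetic


@pytest.fixture(scope="session")
def fixture_dataset():
    """The deterministic 144-venue structured example extract."""
    return fixtures.structured_example_dataset()


@pytest.fixture(scope="session")
def ny_dataset():
    """One seeded draw from the ny-like synthetic preset."""
    cfg = synthetic.ny_like_config(seed=7)
    venues, reviews, truth, sim_truth = synthetic.generate_dataset(cfg)
    return cfg, venues, reviews, truth, sim_truth
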