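import pytest

from sow_interact import features, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.GeneratorConfig(n_positive=8, n_negative=8, n_none=8, seed=42)


@pytest.fixture(scope="session")
def small_events(small_config):
    return synthetic.generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The full replica dataset under default study conditions."""
    return synthetic.generate_dataset(synthetic.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    return features.features_dataframe(default_dataset)
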