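import pytest

from salivome.homology import ClassifierThresholds
from salivome.synthetic_data import GeneratorConfig, generate_truth


@pytest.fixture(scope="session")
def thresholds():
    return ClassifierThresholds()


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete dual-species dataset."""
    return GeneratorConfig(n_genes=300, seed=11)


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_run(small_config):
    from salivome import pipeline

    return pipeline.run(small_config)
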