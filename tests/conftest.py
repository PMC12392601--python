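import pytest

from sexomics.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_counts,
    generate_se_events,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_autosomes=2, genes_per_chrom=12)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_counts(small_annotation, small_config):
    cm, truth = generate_counts(small_annotation, small_config)
    return cm, truth


@pytest.fixture(scope="session")
def small_events(small_annotation, small_config):
    return generate_se_events(small_annotation, small_config)
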