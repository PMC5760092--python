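import pytest

from regulonscope.simulate import SimulationConfig, generate_genome, plant_regulon


@pytest.fixture(scope="session")
def small_config():
    """A 300-gene noiseless study, scaled 1:10 from the defaults."""
    return SimulationConfig(seed=11, n_genes=300, n_operons=30, noise_cv=0.0)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    annotation, operons = small_genome
    return plant_regulon(annotation, operons, n_up=30, n_down=8, n_direct=18,
                         config=small_config)
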