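import pytest

from robustmatch.datasets import load_fermentation_table, load_signature_table
from robustmatch.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A fast study configuration for integration-style tests."""
    return SimulationConfig(
        n_genes=250,
        probes_per_gene=(1, 3),
        n_planted_per_stress=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def table1():
    return load_fermentation_table()


@pytest.fixture(scope="session")
def heat_signature_table():
    return load_signature_table("heat")


@pytest.fixture(scope="session")
def oxidative_signature_table():
    return load_signature_table("oxidative")
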