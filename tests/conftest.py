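import pytest
from hypothesis import settings

from exocipn.digest import ProteinEntry, map_peptides
from exocipn.synthetic_data import SimulationConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: quick to simulate, same structure as the default."""
    return SimulationConfig(
        seed=11,
        n_proteins=60,
        n_differential=4,
        mean_psms_per_protein=8.0,
        shared_peptide_fraction=0.1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_mapping(small_dataset):
    return map_peptides(small_dataset.proteome)


@pytest.fixture
def tiny_db():
    """Two proteins sharing one peptide, each with one unique peptide."""
    return [
        ProteinEntry("P1", "AAAAAAAK" + "CCCCCCCR"),
        ProteinEntry("P2", "DDDDDDDK" + "CCCCCCCR"),
    ]
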