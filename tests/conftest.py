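import pytest

from tatkit.biodistribution import load_nuclide_table
from tatkit.core_io import StudyConfig


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig(seed=0)


@pytest.fixture(scope="session")
def nuclide_data(config):
    return load_nuclide_table(config.nuclide_table_path)


@pytest.fixture(scope="session")
def nuclides(nuclide_data):
    return nuclide_data[0]


@pytest.fixture(scope="session")
def ac225_chain(nuclide_data):
    return nuclide_data[1]["Ac-225"]
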