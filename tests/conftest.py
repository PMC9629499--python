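import logging

import pytest
from hypothesis import settings

from ferrohab import ActivityModel, SpeciesTable, build_grid
from ferrohab.synthetic import make_table1_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# the fixture table intentionally carries a published-table inconsistency;
# keep its load warning out of test output
logging.getLogger("ferrohab.strains").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def species_table():
    return SpeciesTable.default()


@pytest.fixture(scope="session")
def activities():
    return ActivityModel()


@pytest.fixture(scope="session")
def table1_db():
    return make_table1_fixture()


@pytest.fixture(scope="session")
def h2_goethite_grid():
    return build_grid("hydrogen", "goethite")


@pytest.fixture(scope="session")
def h2_ferrihydrite_grid():
    return build_grid("hydrogen", "ferrihydrite")
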