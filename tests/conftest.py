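import pytest

from arborcarbon.fixtures import FixtureSpec, generate_growth_params, generate_management
from arborcarbon.parameters import load_emission_factors, load_species_table
from arborcarbon.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def species_records():
    return load_species_table()


@pytest.fixture(scope="session")
def emission_factors():
    return load_emission_factors()


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def management(fixture_spec, species_records):
    return generate_management(fixture_spec, [r.name for r in species_records])


@pytest.fixture(scope="session")
def growth_params(fixture_spec, species_records, management):
    return generate_growth_params(fixture_spec, species_records, management)


@pytest.fixture(scope="session")
def pwf_run():
    """Full national run, new plantations as public-welfare forests."""
    return run_pipeline(RunConfig(seed=7, new_forest_class="public_welfare"), write=False)


@pytest.fixture(scope="session")
def commercial_run():
    """Full national run, new plantations as commercial forests."""
    return run_pipeline(RunConfig(seed=7, new_forest_class="commercial"), write=False)
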