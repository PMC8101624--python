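import pytest

from enhpro.fixture import make_table1_fixture
from enhpro.pipeline import run_pipeline
from enhpro.simulate import SimulationSpec, simulate


@pytest.fixture(scope="session")
def table1(tmp_path_factory):
    """The deterministic miniature-genome bundle encoding the published Tier-1 set."""
    return make_table1_fixture(tmp_path_factory.mktemp("table1_fixture"))


@pytest.fixture(scope="session")
def table1_default_run(table1):
    return run_pipeline(table1.config, table1.bundle)


@pytest.fixture(scope="session")
def table1_relaxed_run(table1):
    return run_pipeline(table1.relaxed_config, table1.bundle)


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Default seeded synthetic bundle with planted truth labels."""
    return simulate(SimulationSpec(rng_seed=1), tmp_path_factory.mktemp("simbundle"))


@pytest.fixture(scope="session")
def sim_run(sim):
    return run_pipeline(sim.config, sim.bundle)
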