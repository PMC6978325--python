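import pytest

from duicompare.published import assemble_all
from duicompare.simulate import SimulationConfig, simulate_pair


@pytest.fixture(scope="session")
def published_genomes():
    """The four deposited study genomes rebuilt from the packaged
    annotation tables (coordinate- and codon-exact; filler sequence)."""
    return assemble_all()


@pytest.fixture(scope="session")
def sim_pair():
    """One default simulated F/M pair with its planted truth."""
    return simulate_pair(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def sim_f(sim_pair):
    return sim_pair[0]


@pytest.fixture(scope="session")
def sim_m(sim_pair):
    return sim_pair[1]
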