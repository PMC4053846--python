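import pytest

from editoscreen.fixtures import load_ess_table1
from editoscreen.synthetic_data import SimulationConfig, simulate_ortholog_pair


@pytest.fixture(scope="session")
def ess_table1():
    return load_ess_table1()


@pytest.fixture(scope="session")
def default_ortholog_pair():
    """One generated two-species dataset shared across tests (seed 1)."""
    cfg = SimulationConfig(seed=1)
    qg, sg, truth = simulate_ortholog_pair(cfg)
    return cfg, qg, sg, truth
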