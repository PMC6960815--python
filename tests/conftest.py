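import numpy as np
import pytest

from sbris import build_topology, engine


@pytest.fixture(scope="session")
def topo50():
    return build_topology(50)


@pytest.fixture(scope="session")
def topo4():
    return build_topology(4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session", autouse=True)
def warm_kernel():
    """Compile the Monte Carlo kernel once before timing-sensitive tests."""
    s = engine.SimulationSettings(mode="sgcmc", pH=7.0, n_steps=2_000,
                                  n_equilibration=500, n_replicates=1,
                                  elastic_sampling=True, seed=0)
    engine.run_simulation(s, build_topology(2))
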