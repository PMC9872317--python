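import pytest

from spermre.simulate import SimulationConfig, simulate_abundances


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated study shared across tests (seed-fixed)."""
    cfg = SimulationConfig(seed=11, n_res=600)
    sperm, oocyte, zygote, truth = simulate_abundances(cfg)
    return cfg, sperm, oocyte, zygote, truth
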