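import pytest

from hetdomain import simulate


@pytest.fixture(scope="session")
def sim_cfg():
    return simulate.SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_ann(sim_cfg):
    return simulate.generate_annotation(sim_cfg)


@pytest.fixture(scope="session")
def sim_tracks(sim_cfg, sim_ann):
    return simulate.generate_tracks(sim_cfg, sim_ann)


@pytest.fixture(scope="session")
def sim_density(sim_cfg, sim_ann):
    return simulate.generate_readdensity(sim_cfg, sim_ann)


@pytest.fixture(scope="session")
def sim_expression(sim_cfg, sim_ann):
    return simulate.generate_expression(sim_cfg, sim_ann)
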