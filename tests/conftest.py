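import numpy as np
import pytest

from heatdlnm import (
    SimConfig,
    TrueSurface,
    build_crossbasis,
    build_design,
    find_mmt,
    fit_quasipoisson,
    simulate_counts,
    simulate_weather,
)

SEED = 20260927


@pytest.fixture(scope="session")
def surface():
    return TrueSurface()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=SEED)


@pytest.fixture(scope="session")
def weather(sim_config):
    return simulate_weather(sim_config)


@pytest.fixture(scope="session")
def series(weather, surface, sim_config):
    return simulate_counts(weather, surface, sim_config)


@pytest.fixture(scope="session")
def crossbasis(series):
    return build_crossbasis(series.tmean)


@pytest.fixture(scope="session")
def fitted(series, crossbasis):
    fit = fit_quasipoisson(build_design(series, crossbasis), crossbasis)
    find_mmt(fit)
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
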