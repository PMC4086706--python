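import warnings

import pytest

import fluxkit as fk
from fluxkit import fixtures as fx


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # fixture media declare set-level nutrients (sulfate, iron) that the
    # desk-scale network does not metabolize; the skip warnings are expected
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*absent from network.*")
        yield


@pytest.fixture(scope="session")
def core_problem():
    return fx.core_energy_problem(fx.ECOCYC_CONVENTION)


@pytest.fixture(scope="session")
def core_problem_ijo():
    return fx.core_energy_problem(fx.IJO_CONVENTION)


@pytest.fixture(scope="session")
def fermentation_model():
    return fx.build_fermentation_network()


@pytest.fixture(scope="session")
def fermentation_aerobic():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*absent from network.*")
        return fx.fermentation_problem()


@pytest.fixture(scope="session")
def fermentation_anaerobic():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*absent from network.*")
        return fx.fermentation_problem(oxygen_bound=0.0)


@pytest.fixture(scope="session")
def biomass():
    return fx.fermentation_biomass()


@pytest.fixture(scope="session")
def growth_network(fermentation_aerobic, biomass):
    return fk.assemble_biomass(fermentation_aerobic, biomass)
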