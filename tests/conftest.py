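import pytest

import nanogsim as ng


@pytest.fixture(scope="session")
def fluct():
    return ng.preset("fluctuation")


@pytest.fixture(scope="session")
def osc():
    return ng.preset("oscillation")


@pytest.fixture(scope="session")
def os_high(fluct):
    """Operating Oct4-Sox2 level (upper stable root), shared by scenarios."""
    return ng.os_star(fluct)


@pytest.fixture(scope="session")
def fluct_thresholds(fluct):
    return ng.default_thresholds(fluct)


@pytest.fixture(scope="session")
def osc_thresholds(osc):
    return ng.default_thresholds(osc)


@pytest.fixture(scope="session")
def limit_cycle(osc):
    cyc = ng.find_limit_cycle(osc)
    assert cyc.found
    return cyc


@pytest.fixture(scope="session")
def fluct_residence(fluct):
    """Long fluctuation-scenario run, >=400 uncensored LOW sojourns."""
    return ng.residence_analysis(fluct, seed=101, min_sojourns=400)


@pytest.fixture(scope="session")
def osc_residence(osc):
    """Long oscillation-scenario run, >=300 uncensored LOW sojourns."""
    return ng.residence_analysis(osc, seed=101, min_sojourns=300, dt=5e-3)
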