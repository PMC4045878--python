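import pytest

from pduflux.simulate import calibrate_scenario, simulate_with_info


@pytest.fixture(scope="session")
def wt_ph7():
    """Noiseless wild-type pH-7 fed-batch run (config, series, run info)."""
    cfg = calibrate_scenario("wt_ph7")
    series, info = simulate_with_info(cfg)
    return cfg, series, info


@pytest.fixture(scope="session")
def mutant_ph7():
    """Noiseless RPRB3007 pH-7 fed-batch run (config, series, run info)."""
    cfg = calibrate_scenario("mutant_ph7")
    series, info = simulate_with_info(cfg)
    return cfg, series, info
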