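import logging

import pytest

from growthlaw.simulate import SimSpec, simulate_group


@pytest.fixture(autouse=True)
def _quiet_pipeline_logs(caplog):
    logging.getLogger("growthlaw").setLevel(logging.ERROR)


@pytest.fixture
def noiseless_spec():
    """A generator spec with every stochastic term switched off."""
    return SimSpec(od_noise=0.0, gfp_noise=0.0,
                   day_mu_sigma=0.0, day_crp_sigma=0.0, seed=0)


@pytest.fixture
def noiseless_group(noiseless_spec):
    """One clean crp/sigma70/promoterless analysis group (mu=0.6, CRP*=1)."""
    return simulate_group(noiseless_spec)
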