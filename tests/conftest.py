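import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from preterm_bia import Arm, Perspective, default_fixture, run_cohort, run_psa

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_ps():
    return default_fixture()


@pytest.fixture(scope="session")
def base_traces(fixture_ps):
    return {arm: run_cohort(fixture_ps, arm) for arm in Arm}


@pytest.fixture(scope="session")
def psa500(fixture_ps):
    """Scaled-down 500-iteration payer PSA shared across tests."""
    return run_psa(fixture_ps, Perspective.payer, n_iter=500, seed=29)


@pytest.fixture(scope="session")
def microsim_soc(fixture_ps):
    """One 100,000-individual microsimulation of the SoC arm."""
    from microsim import microsimulate

    return microsimulate(fixture_ps, Arm.SOC, n=100_000, seed=11)
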