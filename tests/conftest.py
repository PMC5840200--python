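import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loosematch import PopulationSpec, Scenario

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

#: study conditions shared across tests
STUDY_PREVALENCE = 0.1
STUDY_P_E = 0.3


@pytest.fixture(scope="session")
def pop_gap20() -> PopulationSpec:
    """Strong age-exposure association: 20-year mean-age gap."""
    return PopulationSpec(p_e=STUDY_P_E, mu0=50.0, mu1=70.0, sigma=10.0)


@pytest.fixture(scope="session")
def pop_gap5() -> PopulationSpec:
    """Weak age-exposure association: 5-year mean-age gap."""
    return PopulationSpec(p_e=STUDY_P_E, mu0=65.0, mu1=70.0, sigma=10.0)


@pytest.fixture(scope="session")
def scenario_alt_gap5() -> Scenario:
    return Scenario(mu0=65.0, or_exposure=1.5, or_age_per10=2.0, caliper_d=2, n_cases=400)


@pytest.fixture(scope="session")
def small_matched_dataset(scenario_alt_gap5):
    """One modest matched dataset with an informative age caliper (d=2)."""
    from loosematch import simulate_matched_dataset

    return simulate_matched_dataset(scenario_alt_gap5, np.random.default_rng(2024))
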