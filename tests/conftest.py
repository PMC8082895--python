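import numpy as np
import pytest

from colocea import default_paper_parameters, make_strategy
from colocea.config import ParameterSet
from colocea.states import HealthState
from colocea.strategies import PUREVU, SOC


@pytest.fixture(scope="session")
def base_params():
    return default_paper_parameters("medicare")


@pytest.fixture(scope="session")
def private_params():
    return default_paper_parameters("private")


@pytest.fixture(scope="session")
def soc(base_params):
    return make_strategy(SOC, "medicare", base_params)


@pytest.fixture(scope="session")
def purevu(base_params):
    return make_strategy(PUREVU, "medicare", base_params)


@pytest.fixture(scope="session")
def geometric_toy():
    """Survive with probability 0.9 per year, utility 1, no discounting.

    Started 100% in NONCOMPLIANT_WITH_SYSTEM with all disease transitions
    switched off, the cohort shrinks geometrically and the expected
    (undiscounted) QALYs over 24 cycles are sum_{t<24} 0.9^t.
    """
    params = ParameterSet(
        p_compliance_screening=0.0,
        p_adenoma_prevalence=0.0,
        p_progression_adenoma_to_early=0.0,
        p_death_other_annual=0.1,
        discount_rate=0.0,
        horizon_years=24,
        cost_early_crc_annual=0.0,
        cost_advanced_crc_annual=0.0,
        cost_remission_annual=0.0,
        utility_by_state={
            "no_crc": 1.0,
            "adenoma_surveillance": 1.0,
            "early_crc": 1.0,
            "advanced_crc": 1.0,
            "remission": 1.0,
            "death": 0.0,
        },
    )
    start = np.zeros(len(HealthState))
    start[HealthState.NONCOMPLIANT_WITH_SYSTEM] = 1.0
    expected_qaly = sum(0.9**t for t in range(24))
    return params, start, expected_qaly


def random_valid_parameters(rng: np.random.Generator) -> ParameterSet:
    """A random parameter set satisfying every schema invariant."""
    u = rng.uniform
    onset_budget = 1.0
    p = ParameterSet(
        p_compliance_screening=u(0.05, 0.95),
        p_inadequate_prep_soc=u(0.0, 0.6),
        p_inadequate_prep_purevu=u(0.0, 0.3),
        p_repeat_after_inadequate=u(0.0, 1.0),
        p_adenoma_prevalence=u(0.05, 0.45),
        p_adenoma_prevalence_surveillance=u(0.0, 0.3),
        p_progression_adenoma_to_early=u(0.0, 0.08),
        p_progression_early_to_advanced=u(0.0, 0.2),
        p_early_to_remission=u(0.0, 0.4),
        p_remission_to_advanced=u(0.0, 0.1),
        p_presentation_advanced_unscreened=u(0.0, 0.9),
        p_presentation_advanced_screened=u(0.0, 0.5),
        p_lapse_surveillance=u(0.0, 1.0),
        rr_onset_screened=u(0.0, 1.0),
        rr_onset_surveillance=u(0.0, 1.0),
        p_complication=u(0.0, 0.02),
        p_death_other_annual=u(0.0, 0.08),
        cost_colonoscopy_dx=u(100, 3000),
        cost_early_crc_annual=u(0, 1e5),
        cost_advanced_crc_annual=u(0, 5e5),
        payer_multiplier=u(1.0, 2.5),
        discount_rate=u(0.0, 0.08),
        horizon_years=int(rng.integers(5, 45)),
        screening_interval_years=int(rng.integers(1, 15)),
    )
    return p
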