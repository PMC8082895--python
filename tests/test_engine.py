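import numpy as np
import pytest

from colocea.config import ParameterSet
from colocea.engine import (
    accrue_outcomes,
    build_transition_matrix,
    cumulative_incidence,
    discount_factor,
    run_arm,
    run_cohort,
    trace_to_frame,
)
from colocea.states import ABSORBING_STATES, HealthState, N_STATES
from colocea.strategies import PUREVU, SOC, make_strategy

from conftest import random_valid_parameters


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,t,expected",
        [(0.03, 0, 1.0), (0.0, 17, 1.0), (0.03, 1, 1 / 1.03), (0.03, 2, 1.03**-2)],
    )
    def test_values(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=1e-12)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.03, -1)
        with pytest.raises(ValueError):
            discount_factor(-0.01, 3)


class TestTransitionMatrix:
    def test_rows_sum_to_one_for_random_parameters(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            params = random_valid_parameters(rng)
            arm = SOC if rng.random() < 0.5 else PUREVU
            strat = make_strategy(arm, "medicare", params)
            stage = int(rng.integers(0, params.horizon_years))
            M = build_transition_matrix(params, strat, stage).probs
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert (M >= -1e-12).all()

    def test_absorbing_states_are_unit_rows(self, base_params, soc):
        M = build_transition_matrix(base_params, soc, 0).probs
        for s in ABSORBING_STATES:
            expected = np.zeros(N_STATES)
            expected[s] = 1.0
            assert np.array_equal(M[s], expected)

    def test_screening_only_at_interval_stages(self, base_params, soc):
        S = HealthState
        M_on = build_transition_matrix(base_params, soc, 0).probs
        M_off = build_transition_matrix(base_params, soc, 3).probs
        assert M_on[S.COMPLIANT_SCREENING, S.ADENOMA_SURVEILLANCE] > 0
        assert M_off[S.COMPLIANT_SCREENING, S.ADENOMA_SURVEILLANCE] == 0

    def test_nonattenders_lapse_only_at_repeat_rounds(self, base_params, soc):
        S = HealthState
        M10 = build_transition_matrix(base_params, soc, 10).probs
        M0 = build_transition_matrix(base_params, soc, 0).probs
        # at stage 10, the (1 - compliance) skippers lapse on top of failures
        assert M10[S.COMPLIANT_SCREENING, S.NONCOMPLIANT_POST_COLONOSCOPY] > (
            M0[S.COMPLIANT_SCREENING, S.NONCOMPLIANT_POST_COLONOSCOPY]
        )

    def test_negative_stage_rejected(self, base_params, soc):
        with pytest.raises(ValueError):
            build_transition_matrix(base_params, soc, -1)


class TestRunCohort:
    def test_conservation_and_monotone_death(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            params = random_valid_parameters(rng)
            strat = make_strategy(PUREVU, "medicare", params)
            trace = run_cohort(params, strat, validate=False)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert (trace.occupancy >= -1e-12).all()
            for s in ABSORBING_STATES:
                assert (np.diff(trace.occupancy[:, s]) >= -1e-12).all()

    def test_dead_cohort_accrues_nothing(self, base_params, soc):
        start = np.zeros(N_STATES)
        start[HealthState.DEATH_OTHER] = 1.0
        trace = run_cohort(base_params, soc, initial_occupancy=start)
        assert trace.cycle_cost.sum() == 0.0
        assert trace.cycle_qaly.sum() == 0.0

    def test_geometric_toy_closed_form(self, geometric_toy, soc):
        params, start, expected = geometric_toy
        trace = run_cohort(params, soc, initial_occupancy=start)
        assert trace.cycle_qaly.sum() == pytest.approx(expected, abs=1e-12)

    def test_bad_initial_occupancy_rejected(self, base_params, soc):
        with pytest.raises(ValueError):
            run_cohort(base_params, soc, initial_occupancy=np.ones(N_STATES))

    def test_invalid_horizon_rejected(self, base_params, soc):
        with pytest.raises(ValueError):
            run_cohort(base_params.replace(horizon_years=0), soc, validate=False)


class TestAccrual:
    def test_zero_discount_equals_plain_sums(self, base_params, soc):
        p = base_params.replace(discount_rate=0.0)
        trace = run_cohort(p, soc)
        res = accrue_outcomes(trace, p, soc)
        assert res.total_cost == pytest.approx(trace.cycle_cost.sum())
        assert res.total_qaly == pytest.approx(trace.cycle_qaly.sum())

    def test_discounting_never_increases_totals(self, base_params, soc):
        undisc = run_arm(base_params.replace(discount_rate=0.0), soc)
        disc = run_arm(base_params, soc)
        assert disc.total_cost < undisc.total_cost
        assert disc.total_qaly < undisc.total_qaly

    def test_zero_utilities_zero_qalys(self, base_params, soc):
        p = base_params.replace(
            utility_by_state={k: 0.0 for k in base_params.utility_by_state}
        )
        assert run_arm(p, soc).total_qaly == 0.0

    def test_cost_per_qaly_ratio(self, base_params, soc):
        res = run_arm(base_params, soc)
        assert res.cost_per_qaly == pytest.approx(res.total_cost / res.total_qaly)


class TestCumulativeIncidence:
    def test_no_progression_no_incidence(self, base_params, soc):
        p = base_params.replace(p_progression_adenoma_to_early=0.0)
        trace = run_cohort(p, soc)
        assert cumulative_incidence(trace, HealthState.EARLY_CRC) == 0.0

    def test_single_inflow_bookkeeping(self, soc):
        # all mass moves to EARLY_CRC at the first onset opportunity
        p = ParameterSet(
            p_compliance_screening=0.0,
            p_adenoma_prevalence=1.0,
            p_progression_adenoma_to_early=1.0,
            p_presentation_advanced_unscreened=0.0,
            p_death_other_annual=0.0,
            p_progression_early_to_advanced=0.0,
            p_early_to_remission=0.0,
            horizon_years=5,
        )
        trace = run_cohort(p, soc, validate=False)
        assert cumulative_incidence(trace, HealthState.EARLY_CRC) == pytest.approx(1.0)
        assert trace.inflow_early[0] == pytest.approx(1.0)

    def test_non_crc_state_rejected(self, base_params, soc):
        trace = run_cohort(base_params, soc)
        with pytest.raises(ValueError):
            cumulative_incidence(trace, HealthState.REMISSION)

    def test_purevu_lowers_both_incidences(self, base_params, soc, purevu):
        s = run_arm(base_params, soc)
        v = run_arm(base_params, purevu)
        assert v.cum_incidence_early_crc < s.cum_incidence_early_crc
        assert v.cum_incidence_advanced_crc < s.cum_incidence_advanced_crc


class TestTransitionProperties:
    """Structural invariants under arbitrary valid behavioural parameters."""

    from hypothesis import given, settings, strategies as st

    @given(
        compliance=st.floats(0.0, 1.0),
        inadequate=st.floats(0.0, 1.0),
        repeat=st.floats(0.0, 1.0),
        prevalence=st.floats(0.0, 1.0),
        progression=st.floats(0.0, 0.1),
        stage=st.integers(0, 39),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_rows_stay_stochastic(self, compliance, inadequate, repeat, prevalence,
                                  progression, stage):
        params = ParameterSet(
            p_compliance_screening=compliance,
            p_inadequate_prep_soc=inadequate,
            p_repeat_after_inadequate=repeat,
            p_adenoma_prevalence=prevalence,
            p_progression_adenoma_to_early=progression,
        )
        for arm in (SOC, PUREVU):
            M = build_transition_matrix(params, make_strategy(arm, "medicare", params), stage).probs
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert (M >= -1e-12).all() and (M <= 1 + 1e-12).all()

    @given(rate=st.floats(0.0, 0.5), t=st.integers(0, 200))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_discount_factor_bounds(self, rate, t):
        v = discount_factor(rate, t)
        assert 0.0 < v <= 1.0
        if t > 0 and rate > 1e-9:  # below float resolution (1+r)^-t rounds to 1
            assert v < 1.0


def test_trace_export_layout(base_params, soc):
    trace = run_cohort(base_params, soc)
    df = trace_to_frame(trace)
    assert len(df) == base_params.horizon_years
    assert list(df.columns[:1]) == ["stage"]
    for col in ("cycle_cost", "cycle_qaly", "discounted_cost", "discounted_qaly"):
        assert col in df.columns
    state_cols = [s.name.lower() for s in HealthState]
    assert df[state_cols].sum(axis=1).round(9).eq(1.0).all()
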