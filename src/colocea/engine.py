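"""Deterministic cohort engine: stage-dependent transitions and accrual.

The chain is time-inhomogeneous: a fresh transition matrix is generated for
every annual cycle, embedding the colonoscopy decision tree at screening
stages (years 0, 10, 20 by default) and only natural-history and mortality
transitions elsewhere.  Remaining life expectancy without CRC is realised as
the model horizon itself (deterministic-lifespan assumption, see
docs/methods.md); cancer states carry their own annual death probabilities
chosen to reproduce the 23- and 4.8-year life expectancies.

Screening behaviour embedded in the matrices:

* at stage 0 the compliant fraction of the cohort attends its index exam;
* at later screening stages, compliant individuals re-attend with the
  screening-compliance probability and otherwise lapse
  (``NONCOMPLIANT_POST_COLONOSCOPY``);
* an inadequately prepped exam that is never repeated ends the individual's
  participation in the programme (a guideline failure) unless the adenoma
  was detected despite the poor preparation;
* a detected adenoma is removed and the individual enters annual
  colonoscopic surveillance, which can itself be abandoned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    ParameterSet,
    ValidationError,
    excess_mortality_early,
    mortality_advanced,
    validate_parameters,
)
from .states import ABSORBING_STATES, HealthState, N_STATES, UTILITY_KEY
from .strategies import Strategy, colonoscopy_episode_cost, episode_profile

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "ArmResult",
    "build_transition_matrix",
    "run_cohort",
    "run_arm",
    "discount_factor",
    "accrue_outcomes",
    "cumulative_incidence",
    "trace_to_frame",
]

_ROW_TOL = 1e-12


def discount_factor(rate: float, t: int) -> float:
    """Present-value factor ``(1 + rate) ** -t`` for a stage index ``t``."""
    if t < 0:
        raise ValueError("stage index must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-t)


def screening_attendance(params: ParameterSet, stage: int) -> float:
    """Probability that a COMPLIANT_SCREENING individual is examined at ``stage``."""
    if stage % params.screening_interval_years != 0:
        return 0.0
    return 1.0 if stage == 0 else params.p_compliance_screening


def surveillance_exam_probability(params: ParameterSet) -> float:
    """Annual probability that an ADENOMA_SURVEILLANCE individual is examined."""
    return params.surveillance_compliance / params.surveillance_interval_years


@dataclass(frozen=True)
class TransitionMatrix:
    stage: int
    probs: np.ndarray  # (N_STATES, N_STATES)

    def __post_init__(self) -> None:
        P = self.probs
        if P.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be square over the nine states")
        if (P < -_ROW_TOL).any() or (P > 1 + _ROW_TOL).any():
            raise ValidationError("transition probabilities outside [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("transition-matrix rows must sum to 1")


def _onset_rates(params: ParameterSet) -> tuple[float, float]:
    """Annual CRC-onset probabilities (unprotected, under surveillance)."""
    o_un = params.p_adenoma_prevalence * params.p_progression_adenoma_to_early
    o_as = o_un * params.rr_onset_surveillance
    return o_un, o_as


def _split_onset(mass: float, onset: float, frac_advanced: float) -> tuple[float, float, float]:
    """Split a state mass into (remaining, to EARLY_CRC, to ADVANCED_CRC)."""
    to_ec = mass * onset * (1.0 - frac_advanced)
    to_ac = mass * onset * frac_advanced
    return mass - to_ec - to_ac, to_ec, to_ac


def build_transition_matrix(params: ParameterSet, strategy: Strategy, stage: int) -> TransitionMatrix:
    """One-year transition matrix for ``stage`` years after cohort entry."""
    if stage < 0:
        raise ValueError("stage must be >= 0")
    S = HealthState
    P = np.zeros((N_STATES, N_STATES))

    lam = params.p_death_other_annual
    o_un, o_as = _onset_rates(params)
    f_un = params.p_presentation_advanced_unscreened
    f_s = params.p_presentation_advanced_screened
    q_ec = excess_mortality_early(params)
    q_ac = mortality_advanced(params)
    prof = episode_profile(params, strategy)
    s_i = dict(params.detection_inadequate)["sensitivity"]
    p_aden = params.p_adenoma_prevalence

    def alive_row(row: int, masses: dict[int, float]) -> None:
        """Fill ``row`` given pre-mortality destination masses; applies
        other-cause mortality multiplicatively and checks the residual."""
        total = sum(masses.values())
        if total > 1.0 + 1e-9:
            raise ValidationError(
                f"negative residual probability in row {S(row).name} at stage {stage}"
            )
        for dest, m in masses.items():
            P[row, dest] += m * (1.0 - lam)
        P[row, S.DEATH_OTHER] += total * lam
        # numerical guard: force exact row sum
        P[row, row] += 1.0 - P[row].sum()

    # --- COMPLIANT_SCREENING -------------------------------------------
    att = screening_attendance(params, stage)
    lapse_nonattender = stage > 0 and stage % params.screening_interval_years == 0
    to_as = att * p_aden * prof.p_detect_given_adenoma
    to_npc_fail = att * prof.frac_inadequate_final * (1.0 - p_aden * s_i)
    to_npc_skip = (1.0 - att) if lapse_nonattender else 0.0
    cs_rem = 1.0 - to_as - to_npc_fail - to_npc_skip

    cs_stay, cs_ec, cs_ac = _split_onset(cs_rem, o_un * params.rr_onset_screened, f_s)
    npc_new = to_npc_fail + to_npc_skip
    npc_stay, npc_ec, npc_ac = _split_onset(npc_new, o_un, f_un)
    as_stay, as_ec, as_ac = _split_onset(to_as, o_as, f_s)
    alive_row(
        S.COMPLIANT_SCREENING,
        {
            S.COMPLIANT_SCREENING: cs_stay,
            S.ADENOMA_SURVEILLANCE: as_stay,
            S.NONCOMPLIANT_POST_COLONOSCOPY: npc_stay,
            S.EARLY_CRC: cs_ec + npc_ec + as_ec,
            S.ADVANCED_CRC: cs_ac + npc_ac + as_ac,
        },
    )

    # --- lapsed / never-screened ----------------------------------------
    for state in (S.NONCOMPLIANT_POST_COLONOSCOPY, S.NONCOMPLIANT_WITH_SYSTEM):
        stay, ec, ac = _split_onset(1.0, o_un, f_un)
        alive_row(state, {state: stay, S.EARLY_CRC: ec, S.ADVANCED_CRC: ac})

    # --- ADENOMA_SURVEILLANCE --------------------------------------------
    p_exam_year = 1.0 / params.surveillance_interval_years
    skip = p_exam_year * (1.0 - params.surveillance_compliance)
    lapse = skip * params.p_lapse_surveillance
    as_rem, as_ec2, as_ac2 = _split_onset(1.0 - lapse, o_as, f_s)
    npc_rem, npc_ec2, npc_ac2 = _split_onset(lapse, o_un, f_un)
    alive_row(
        S.ADENOMA_SURVEILLANCE,
        {
            S.ADENOMA_SURVEILLANCE: as_rem,
            S.NONCOMPLIANT_POST_COLONOSCOPY: npc_rem,
            S.EARLY_CRC: as_ec2 + npc_ec2,
            S.ADVANCED_CRC: as_ac2 + npc_ac2,
        },
    )

    # --- cancer states ----------------------------------------------------
    # other-cause mortality competes only for patients without a listed
    # cancer event in the cycle (same convention as the microsimulation)
    ec_events = params.p_progression_early_to_advanced + params.p_early_to_remission + q_ec
    P[S.EARLY_CRC, S.ADVANCED_CRC] = params.p_progression_early_to_advanced
    P[S.EARLY_CRC, S.REMISSION] = params.p_early_to_remission
    P[S.EARLY_CRC, S.DEATH_CRC] = q_ec
    P[S.EARLY_CRC, S.DEATH_OTHER] = lam * (1.0 - ec_events)
    P[S.EARLY_CRC, S.EARLY_CRC] = 1.0 - P[S.EARLY_CRC].sum()
    if P[S.EARLY_CRC, S.EARLY_CRC] < -_ROW_TOL:
        raise ValidationError("negative residual probability in EARLY_CRC row")

    P[S.ADVANCED_CRC, S.DEATH_CRC] = q_ac
    P[S.ADVANCED_CRC, S.DEATH_OTHER] = lam * (1.0 - q_ac)
    P[S.ADVANCED_CRC, S.ADVANCED_CRC] = 1.0 - P[S.ADVANCED_CRC].sum()

    P[S.REMISSION, S.ADVANCED_CRC] = params.p_remission_to_advanced
    P[S.REMISSION, S.DEATH_OTHER] = lam * (1.0 - params.p_remission_to_advanced)
    P[S.REMISSION, S.REMISSION] = 1.0 - P[S.REMISSION].sum()

    for state in ABSORBING_STATES:
        P[state, state] = 1.0

    return TransitionMatrix(stage=stage, probs=P)


@dataclass
class CohortTrace:
    """Stage-by-state occupancy with per-stage (un)discounted accruals.

    ``occupancy`` has ``horizon + 1`` rows; accrual vectors have ``horizon``
    entries, one per cycle, computed from the occupancy at the start of the
    cycle.  ``inflow_early``/``inflow_advanced`` record new entrants per
    cycle into the cancer states.
    """

    occupancy: np.ndarray
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray
    discounted_cost: np.ndarray
    discounted_qaly: np.ndarray
    inflow_early: np.ndarray
    inflow_advanced: np.ndarray


def _state_utilities(params: ParameterSet) -> np.ndarray:
    util = dict(params.utility_by_state)
    return np.array([util[UTILITY_KEY[HealthState(i)]] for i in range(N_STATES)])


def _stage_cost(params: ParameterSet, strategy: Strategy, stage: int, occ: np.ndarray) -> float:
    S = HealthState
    att = screening_attendance(params, stage)
    cost = 0.0
    if att > 0.0:
        ep = colonoscopy_episode_cost(params, strategy)
        cost += occ[S.COMPLIANT_SCREENING] * att * ep.expected_cost
    p_surv_exam = surveillance_exam_probability(params)
    if p_surv_exam > 0.0:
        ep_s = colonoscopy_episode_cost(
            params, strategy, p_adenoma=params.p_adenoma_prevalence_surveillance
        )
        cost += occ[S.ADENOMA_SURVEILLANCE] * p_surv_exam * ep_s.expected_cost
    # cancer-care costs: only the fee-schedule share scales with the payer
    m_cancer = 1.0 + (params.payer_multiplier - 1.0) * params.cancer_care_fee_schedule_share
    cost += occ[S.EARLY_CRC] * params.cost_early_crc_annual * m_cancer
    cost += occ[S.ADVANCED_CRC] * params.cost_advanced_crc_annual * m_cancer
    cost += occ[S.REMISSION] * params.cost_remission_annual * m_cancer
    return cost


def run_cohort(
    params: ParameterSet,
    strategy: Strategy,
    initial_occupancy: np.ndarray | None = None,
    validate: bool = True,
) -> CohortTrace:
    """Propagate the cohort over the full horizon.

    The cohort starts split between COMPLIANT_SCREENING and
    NONCOMPLIANT_WITH_SYSTEM by the screening-compliance probability unless
    an explicit ``initial_occupancy`` is given.
    """
    if validate:
        validate_parameters(params).raise_if_failed()
    horizon = params.horizon_years
    if horizon < 1:
        raise ValueError("horizon_years must be >= 1")

    S = HealthState
    if initial_occupancy is None:
        occ0 = np.zeros(N_STATES)
        occ0[S.COMPLIANT_SCREENING] = params.p_compliance_screening
        occ0[S.NONCOMPLIANT_WITH_SYSTEM] = 1.0 - params.p_compliance_screening
    else:
        occ0 = np.asarray(initial_occupancy, dtype=float)
        if occ0.shape != (N_STATES,) or abs(occ0.sum() - 1.0) > 1e-9 or (occ0 < 0).any():
            raise ValueError("initial occupancy must be a length-9 distribution")

    utilities = _state_utilities(params)
    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0] = occ0
    cycle_cost = np.zeros(horizon)
    cycle_qaly = np.zeros(horizon)
    inflow_early = np.zeros(horizon)
    inflow_advanced = np.zeros(horizon)

    for t in range(horizon):
        occ = occupancy[t]
        M = build_transition_matrix(params, strategy, t).probs
        nxt = occ @ M
        # half-cycle correction averages start- and end-of-cycle occupancy
        # for the continuous rewards (utilities, annual cancer costs);
        # event-driven screening costs always use start-of-cycle occupancy.
        reward_occ = 0.5 * (occ + nxt) if params.half_cycle_correction else occ
        cycle_cost[t] = _stage_cost(params, strategy, t, occ)
        cycle_qaly[t] = float(reward_occ @ utilities)
        inflow_early[t] = float(np.delete(occ, S.EARLY_CRC) @ np.delete(M[:, S.EARLY_CRC], S.EARLY_CRC))
        inflow_advanced[t] = float(
            np.delete(occ, S.ADVANCED_CRC) @ np.delete(M[:, S.ADVANCED_CRC], S.ADVANCED_CRC)
        )
        occupancy[t + 1] = nxt

    v = np.array([discount_factor(params.discount_rate, t) for t in range(horizon)])
    return CohortTrace(
        occupancy=occupancy,
        cycle_cost=cycle_cost,
        cycle_qaly=cycle_qaly,
        discounted_cost=cycle_cost * v,
        discounted_qaly=cycle_qaly * v,
        inflow_early=inflow_early,
        inflow_advanced=inflow_advanced,
    )


@dataclass(frozen=True)
class ArmResult:
    total_cost: float
    total_qaly: float
    cost_per_qaly: float
    cum_incidence_early_crc: float
    cum_incidence_advanced_crc: float


def cumulative_incidence(trace: CohortTrace, state: HealthState) -> float:
    """Lifetime fraction of the cohort ever entering a cancer state."""
    if state == HealthState.EARLY_CRC:
        return float(trace.inflow_early.sum())
    if state == HealthState.ADVANCED_CRC:
        return float(trace.inflow_advanced.sum())
    raise ValueError("cumulative incidence is defined for the CRC states only")


def accrue_outcomes(trace: CohortTrace, params: ParameterSet, strategy: Strategy) -> ArmResult:
    """Lifetime discounted totals and cumulative cancer incidences."""
    util = dict(params.utility_by_state)
    missing = [k for k in set(UTILITY_KEY.values()) if k not in util]
    if missing:
        raise ValidationError(f"missing utility for state bucket(s): {missing}")
    total_cost = float(trace.discounted_cost.sum())
    total_qaly = float(trace.discounted_qaly.sum())
    return ArmResult(
        total_cost=total_cost,
        total_qaly=total_qaly,
        cost_per_qaly=total_cost / total_qaly if total_qaly > 0 else float("nan"),
        cum_incidence_early_crc=cumulative_incidence(trace, HealthState.EARLY_CRC),
        cum_incidence_advanced_crc=cumulative_incidence(trace, HealthState.ADVANCED_CRC),
    )


def run_arm(params: ParameterSet, strategy: Strategy, validate: bool = True) -> ArmResult:
    """Convenience wrapper: cohort run followed by outcome accrual."""
    trace = run_cohort(params, strategy, validate=validate)
    return accrue_outcomes(trace, params, strategy)


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Stage-by-stage table: occupancy per state plus accrual columns."""
    horizon = trace.cycle_cost.shape[0]
    df = pd.DataFrame(
        trace.occupancy[:horizon],
        columns=[s.name.lower() for s in HealthState],
    )
    df.insert(0, "stage", np.arange(horizon))
    df["cycle_cost"] = trace.cycle_cost
    df["cycle_qaly"] = trace.cycle_qaly
    df["discounted_cost"] = trace.discounted_cost
    df["discounted_qaly"] = trace.discounted_qaly
    return df
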