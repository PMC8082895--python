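"""Synthetic data: individual-level microsimulation and study datasets.

The microsimulation is the Monte-Carlo twin of the cohort engine: patients
walk the same stage-dependent transition structure, but the colonoscopy
episode is resolved event by event (attendance, prep adequacy, device use,
repeat exam, detection, polypectomy, complication), so the expected episode
cost of :func:`colocea.strategies.colonoscopy_episode_cost` and the cohort
occupancy of :func:`colocea.engine.run_cohort` are both checked against an
independent code path.

The study generator emulates a colonoscopy-outcome dataset (age, sex, device
use, cecal intubation, success) with configurable covariate effects for the
propensity module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import ParameterSet, excess_mortality_early, mortality_advanced
from .engine import (
    build_transition_matrix,
    discount_factor,
    screening_attendance,
    surveillance_exam_probability,
)
from .propensity import StudyRecord
from .states import HealthState, N_STATES, UTILITY_KEY
from .strategies import PUREVU, Strategy

__all__ = [
    "PatientTrajectory",
    "SyntheticStudySpec",
    "simulate_patients",
    "occupancy_frequencies",
    "generate_study",
]


@dataclass
class PatientTrajectory:
    patient_id: int
    state_path: np.ndarray  # length horizon + 1
    #: per-patient event counters over the whole trajectory
    n_colonoscopies: int
    n_inadequate_prep: int
    n_repeats: int
    n_polypectomies: int
    n_complications: int
    n_device_uses: int
    cost_accrued: float  # discounted
    qaly_accrued: float  # discounted


def _episode(params: ParameterSet, strategy: Strategy, rng: np.random.Generator,
             p_adenoma: float) -> tuple[str, float, dict[str, int]]:
    """Resolve one colonoscopy episode event by event.

    Returns (disposition, cost, event counts) where disposition is one of
    ``"detected"`` (adenoma found and removed), ``"failed"`` (inadequate,
    never repeated, nothing found) or ``"clear"``.
    """
    m = params.payer_multiplier
    exam_unit = (params.cost_colonoscopy_dx + params.cost_physician) * m
    s_a = dict(params.detection_adequate)["sensitivity"]
    s_i = dict(params.detection_inadequate)["sensitivity"]
    spec_a = dict(params.detection_adequate)["specificity"]

    events = {"exams": 1, "inadequate": 0, "repeats": 0, "polypectomies": 0,
              "complications": 0, "device_uses": 0}
    cost = exam_unit

    if strategy.arm == PUREVU:
        presented_inadequate = rng.random() < strategy.device_use_fraction
        if presented_inadequate:
            events["device_uses"] = 1
            cost += strategy.device_cost
            final_inadequate = rng.random() < strategy.p_inadequate_prep
        else:
            final_inadequate = False
    else:
        final_inadequate = rng.random() < strategy.p_inadequate_prep

    adequate = not final_inadequate
    if final_inadequate:
        events["inadequate"] = 1
        if rng.random() < params.repeat_after_inadequate_effective:
            events["repeats"] = 1
            events["exams"] += 1
            cost += exam_unit
            adequate = True  # repeat exam assumed adequately prepped

    sens = s_a if adequate else s_i
    has_adenoma = rng.random() < p_adenoma
    removal = (rng.random() < sens) if has_adenoma else (rng.random() < 1.0 - spec_a)
    detected_adenoma = has_adenoma and removal
    if removal:
        events["polypectomies"] = 1
        cost += params.cost_colonoscopy_polypectomy * m
    for _ in range(events["exams"]):
        if rng.random() < params.p_complication:
            events["complications"] += 1
            cost += params.cost_complication * m

    if detected_adenoma:
        dispo = "detected"
    elif final_inadequate and events["repeats"] == 0:
        dispo = "failed"
    else:
        dispo = "clear"
    return dispo, cost, events


def _onset_destination(rng: np.random.Generator, onset: float, frac_advanced: float) -> Optional[HealthState]:
    if rng.random() < onset:
        if rng.random() < frac_advanced:
            return HealthState.ADVANCED_CRC
        return HealthState.EARLY_CRC
    return None


def simulate_patients(
    params: ParameterSet,
    strategy: Strategy,
    n: int,
    seed: Optional[int] = None,
) -> list[PatientTrajectory]:
    """Simulate ``n`` patients through the model, event by event."""
    if n < 1:
        raise ValueError("n must be >= 1")
    S = HealthState
    horizon = params.horizon_years
    rng = np.random.default_rng(seed)
    lam = params.p_death_other_annual
    o_un = params.p_adenoma_prevalence * params.p_progression_adenoma_to_early
    o_cs = o_un * params.rr_onset_screened
    o_as = o_un * params.rr_onset_surveillance
    f_un = params.p_presentation_advanced_unscreened
    f_s = params.p_presentation_advanced_screened
    q_ec = excess_mortality_early(params)
    q_ac = mortality_advanced(params)
    m_cancer = 1.0 + (params.payer_multiplier - 1.0) * params.cancer_care_fee_schedule_share
    utilities = {s: dict(params.utility_by_state)[UTILITY_KEY[s]] for s in S}
    p_surv_exam_year = 1.0 / params.surveillance_interval_years
    sigma = params.surveillance_compliance

    out: list[PatientTrajectory] = []
    for pid in range(n):
        state = (
            S.COMPLIANT_SCREENING
            if rng.random() < params.p_compliance_screening
            else S.NONCOMPLIANT_WITH_SYSTEM
        )
        path = np.empty(horizon + 1, dtype=np.int8)
        path[0] = state
        cost = qaly = 0.0
        counters = dict.fromkeys(
            ["exams", "inadequate", "repeats", "polypectomies", "complications", "device_uses"], 0
        )
        for t in range(horizon):
            v = discount_factor(params.discount_rate, t)
            qaly += utilities[state] * v
            nxt = state
            if state == S.COMPLIANT_SCREENING:
                att = screening_attendance(params, t)
                is_round = t % params.screening_interval_years == 0
                if is_round and rng.random() < att:
                    dispo, ep_cost, ev = _episode(params, strategy, rng, params.p_adenoma_prevalence)
                    cost += ep_cost * v
                    for k in counters:
                        counters[k] += ev[k]
                    if dispo == "detected":
                        nxt = S.ADENOMA_SURVEILLANCE
                    elif dispo == "failed":
                        nxt = S.NONCOMPLIANT_POST_COLONOSCOPY
                elif is_round and t > 0:
                    nxt = S.NONCOMPLIANT_POST_COLONOSCOPY
                # onset at the post-screening state's rate
                if nxt == S.COMPLIANT_SCREENING:
                    dest = _onset_destination(rng, o_cs, f_s)
                elif nxt == S.ADENOMA_SURVEILLANCE:
                    dest = _onset_destination(rng, o_as, f_s)
                else:
                    dest = _onset_destination(rng, o_un, f_un)
                if dest is not None:
                    nxt = dest
                if rng.random() < lam:
                    nxt = S.DEATH_OTHER
            elif state == S.ADENOMA_SURVEILLANCE:
                if rng.random() < p_surv_exam_year:
                    if rng.random() < sigma:
                        _, ep_cost, ev = _episode(
                            params, strategy, rng, params.p_adenoma_prevalence_surveillance
                        )
                        cost += ep_cost * v
                        for k in counters:
                            counters[k] += ev[k]
                    elif rng.random() < params.p_lapse_surveillance:
                        nxt = S.NONCOMPLIANT_POST_COLONOSCOPY
                if nxt == S.ADENOMA_SURVEILLANCE:
                    dest = _onset_destination(rng, o_as, f_s)
                else:
                    dest = _onset_destination(rng, o_un, f_un)
                if dest is not None:
                    nxt = dest
                if rng.random() < lam:
                    nxt = S.DEATH_OTHER
            elif state in (S.NONCOMPLIANT_POST_COLONOSCOPY, S.NONCOMPLIANT_WITH_SYSTEM):
                dest = _onset_destination(rng, o_un, f_un)
                if dest is not None:
                    nxt = dest
                if rng.random() < lam:
                    nxt = S.DEATH_OTHER
            elif state == S.EARLY_CRC:
                cost += params.cost_early_crc_annual * m_cancer * v
                u = rng.random()
                if u < q_ec:
                    nxt = S.DEATH_CRC
                elif u < q_ec + params.p_progression_early_to_advanced:
                    nxt = S.ADVANCED_CRC
                elif u < q_ec + params.p_progression_early_to_advanced + params.p_early_to_remission:
                    nxt = S.REMISSION
                elif rng.random() < lam:
                    nxt = S.DEATH_OTHER
            elif state == S.ADVANCED_CRC:
                cost += params.cost_advanced_crc_annual * m_cancer * v
                if rng.random() < q_ac:
                    nxt = S.DEATH_CRC
                elif rng.random() < lam:
                    nxt = S.DEATH_OTHER
            elif state == S.REMISSION:
                cost += params.cost_remission_annual * m_cancer * v
                if rng.random() < params.p_remission_to_advanced:
                    nxt = S.ADVANCED_CRC
                elif rng.random() < lam:
                    nxt = S.DEATH_OTHER
            state = HealthState(nxt)
            path[t + 1] = state
        out.append(
            PatientTrajectory(
                patient_id=pid,
                state_path=path,
                n_colonoscopies=counters["exams"],
                n_inadequate_prep=counters["inadequate"],
                n_repeats=counters["repeats"],
                n_polypectomies=counters["polypectomies"],
                n_complications=counters["complications"],
                n_device_uses=counters["device_uses"],
                cost_accrued=cost,
                qaly_accrued=qaly,
            )
        )
    return out


def occupancy_frequencies(trajectories: Sequence[PatientTrajectory]) -> np.ndarray:
    """(stage x state) state-frequency table across patients."""
    horizon_p1 = trajectories[0].state_path.shape[0]
    freq = np.zeros((horizon_p1, N_STATES))
    for tr in trajectories:
        freq[np.arange(horizon_p1), tr.state_path] += 1.0
    return freq / len(trajectories)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Recipe for a synthetic colonoscopy-outcome study."""

    n: int
    age_mean: float = 60.0
    age_sd: float = 8.0
    p_male: float = 0.54
    p_device: float = 0.5
    #: logistic coefficients of the success model on raw covariates
    coefficients: dict = field(
        default_factory=lambda: {
            "intercept": -2.0,
            "age": 0.03,
            "sex": 0.4,
            "device_used": 0.8,
            "cecal_intubation": 1.5,
        }
    )
    #: beta parameters for the cecal-intubation depth in [0, 1]
    cecal_alpha: float = 8.0
    cecal_beta: float = 1.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("p_male", "p_device"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def generate_study(spec: SyntheticStudySpec) -> list[StudyRecord]:
    """Draw covariates and a logistic success outcome per the spec."""
    rng = np.random.default_rng(spec.seed)
    age = rng.normal(spec.age_mean, spec.age_sd, spec.n)
    sex = (rng.random(spec.n) < spec.p_male).astype(int)
    device = (rng.random(spec.n) < spec.p_device).astype(int)
    cecal = rng.beta(spec.cecal_alpha, spec.cecal_beta, spec.n)
    c = spec.coefficients
    eta = (
        c.get("intercept", 0.0)
        + c.get("age", 0.0) * age
        + c.get("sex", 0.0) * sex
        + c.get("device_used", 0.0) * device
        + c.get("cecal_intubation", 0.0) * cecal
    )
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    success = (rng.random(spec.n) < p).astype(int)
    return [
        StudyRecord(
            age=float(age[i]),
            sex=int(sex[i]),
            device_used=int(device[i]),
            cecal_intubation=float(cecal[i]),
            success=int(success[i]),
        )
        for i in range(spec.n)
    ]
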