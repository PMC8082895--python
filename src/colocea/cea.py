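"""Pairwise cost-effectiveness statistics and national projections.

Two reporting idioms are computed side by side, matching health-economics
practice: the *average* cost-effectiveness ratio of each arm (cost divided
by QALYs) and the *incremental* statistics between arms (delta cost, delta
QALY, ICER, incremental net benefit).  Dominance is classified by the
quadrant of the cost-effectiveness plane.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import ArmResult

__all__ = [
    "ICERResult",
    "NationalProjection",
    "compare",
    "incremental_net_benefit",
    "cost_per_qaly",
    "national_savings",
    "patients_failing_guidelines",
]

INTERVENTION_DOMINATES = "intervention_dominates"
COMPARATOR_DOMINATES = "comparator_dominates"
TRADEOFF_NE = "tradeoff_ne_quadrant"
TRADEOFF_SW = "tradeoff_sw_quadrant"


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str


def classify_dominance(delta_cost: float, delta_qaly: float) -> str:
    """Quadrant of the cost-effectiveness plane for intervention vs comparator."""
    if delta_cost <= 0 and delta_qaly >= 0 and (delta_cost < 0 or delta_qaly > 0):
        return INTERVENTION_DOMINATES
    if delta_cost >= 0 and delta_qaly <= 0 and (delta_cost > 0 or delta_qaly < 0):
        return COMPARATOR_DOMINATES
    if delta_cost > 0 and delta_qaly > 0:
        return TRADEOFF_NE
    if delta_cost < 0 and delta_qaly < 0:
        return TRADEOFF_SW
    return INTERVENTION_DOMINATES  # both deltas zero: indifferent, no trade-off


def compare(intervention: ArmResult, comparator: ArmResult) -> ICERResult:
    """Incremental statistics of ``intervention`` against ``comparator``."""
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qaly - comparator.total_qaly
    icer = dc / dq if dq != 0.0 else None
    return ICERResult(delta_cost=dc, delta_qaly=dq, icer=icer, dominance=classify_dominance(dc, dq))


def incremental_net_benefit(intervention: ArmResult, comparator: ArmResult, wtp: float) -> float:
    """Monetary net benefit ``wtp * dQALY - dCost`` at a willingness-to-pay."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    res = compare(intervention, comparator)
    return wtp * res.delta_qaly - res.delta_cost


def cost_per_qaly(cost: float, qaly: float) -> float:
    """Average cost-effectiveness ratio, rounded to the nearest dollar."""
    if qaly <= 0:
        raise ValueError("QALYs must be > 0 for a cost/QALY ratio")
    return round(cost / qaly)


@dataclass(frozen=True)
class NationalProjection:
    n_colonoscopies_annual: float
    inadequate_rate: float
    per_patient_saving: float

    @property
    def total_saving(self) -> float:
        return self.n_colonoscopies_annual * self.inadequate_rate * self.per_patient_saving


def national_savings(n: float, inadequate_rate: float, per_patient_saving: float) -> float:
    """Annual system-wide saving: volume x inadequate-prep rate x per-patient saving."""
    if n < 0 or per_patient_saving < 0 or not 0 <= inadequate_rate <= 1:
        raise ValueError("inputs must be nonnegative, rate in [0, 1]")
    return NationalProjection(n, inadequate_rate, per_patient_saving).total_saving


def patients_failing_guidelines(n: float, inadequate_rate: float, nonrepeat_complement: float) -> float:
    """Patients with an inadequate prep and no timely repeat exam.

    ``nonrepeat_complement`` is one minus the repeat rate within the
    guideline window (e.g. 0.80 when 19.8% repeat within 4 years).
    """
    if not (0 <= inadequate_rate <= 1 and 0 <= nonrepeat_complement <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if n < 0:
        raise ValueError("count must be >= 0")
    return n * inadequate_rate * nonrepeat_complement
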