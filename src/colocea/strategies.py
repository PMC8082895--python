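"""Strategy arms and the expected cost of one colonoscopy episode.

An *episode* is everything triggered by one scheduled colonoscopy: the index
exam, the possible intra-procedural cleansing device, the possible repeat
exam after an inadequate preparation, polypectomy and complications.  The
two arms differ only in how an inadequately prepped colon is handled:

* **SOC** - the exam proceeds with degraded sensitivity; the patient is asked
  to return for a repeat exam, which happens with probability
  ``p_repeat_after_inadequate``.
* **PureVu** - the cleansing device is deployed in the inadequately-prepped
  fraction of exams (at list price, payer-independent) and restores adequate
  prep in 95% of them; the residual failures follow the SOC repeat pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .config import ParameterSet

__all__ = [
    "Strategy",
    "EpisodeCost",
    "EpisodeProfile",
    "make_strategy",
    "episode_profile",
    "colonoscopy_episode_cost",
    "payer_adjust",
    "SOC",
    "PUREVU",
]


@dataclass(frozen=True)
class Strategy:
    """One analysis arm."""

    name: str
    arm: str  # "soc" | "purevu"
    #: final inadequate-prep probability among device-treated exams
    #: (PureVu) or among all exams (SOC)
    p_inadequate_prep: float
    device_cost: float
    #: fraction of episodes incurring the device cost (the fraction
    #: presenting with an inadequately prepped colon)
    device_use_fraction: float
    payer: str = "medicare"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inadequate_prep <= 1.0:
            raise ValueError("p_inadequate_prep must be in [0, 1]")
        if self.device_cost < 0:
            raise ValueError("device_cost must be >= 0")
        if not 0.0 <= self.device_use_fraction <= 1.0:
            raise ValueError("device_use_fraction must be in [0, 1]")


SOC = "soc"
PUREVU = "purevu"


def make_strategy(arm: str, payer: str = "medicare", params: ParameterSet | None = None) -> Strategy:
    """Build one of the four analysis arms (soc/purevu x medicare/private)."""
    if payer not in ("medicare", "private"):
        raise ValueError(f"unknown payer {payer!r}")
    if params is None:
        params = ParameterSet()
    if arm == SOC:
        return Strategy(
            name=f"SOC ({payer})",
            arm=SOC,
            p_inadequate_prep=params.p_inadequate_prep_soc,
            device_cost=0.0,
            device_use_fraction=0.0,
            payer=payer,
        )
    if arm == PUREVU:
        return Strategy(
            name=f"PureVu ({payer})",
            arm=PUREVU,
            p_inadequate_prep=params.p_inadequate_prep_purevu,
            device_cost=params.cost_purevu_device,
            device_use_fraction=params.p_inadequate_prep_soc,
            payer=payer,
        )
    raise ValueError(f"unknown arm {arm!r}")


@dataclass(frozen=True)
class EpisodeProfile:
    """Branch probabilities of one colonoscopy episode (per attender).

    ``frac_adequate_immediate`` - exams adequate at the index procedure
    (including device rescues); ``frac_repeat`` - inadequate exams followed by
    a repeat exam; ``frac_inadequate_final`` - inadequate exams never
    repeated (these individuals leave the screening programme);
    ``p_detect_given_adenoma`` - overall per-episode sensitivity for a
    prevalent adenoma; ``expected_exams`` - expected number of procedures
    performed (index + repeat).
    """

    frac_adequate_immediate: float
    frac_repeat: float
    frac_inadequate_final: float
    p_detect_given_adenoma: float
    p_false_positive: float
    expected_exams: float


def episode_profile(params: ParameterSet, strategy: Strategy) -> EpisodeProfile:
    repeat = params.repeat_after_inadequate_effective
    s_a = dict(params.detection_adequate)["sensitivity"]
    s_i = dict(params.detection_inadequate)["sensitivity"]
    spec_a = dict(params.detection_adequate)["specificity"]

    if strategy.arm == PUREVU:
        presented_inadequate = strategy.device_use_fraction
        # device rescues (1 - p_inadequate_prep) of treated exams in-session
        inadequate_final = presented_inadequate * strategy.p_inadequate_prep
        adequate_immediate = 1.0 - inadequate_final
    else:
        inadequate_final = strategy.p_inadequate_prep
        adequate_immediate = 1.0 - inadequate_final

    frac_repeat = inadequate_final * repeat
    frac_norepeat = inadequate_final * (1.0 - repeat)
    # repeat exams are assumed adequately prepped
    p_detect = (adequate_immediate + frac_repeat) * s_a + frac_norepeat * s_i
    return EpisodeProfile(
        frac_adequate_immediate=adequate_immediate,
        frac_repeat=frac_repeat,
        frac_inadequate_final=frac_norepeat,
        p_detect_given_adenoma=p_detect,
        p_false_positive=1.0 - spec_a,
        expected_exams=1.0 + frac_repeat,
    )


@dataclass(frozen=True)
class EpisodeCost:
    expected_cost: float
    components: Mapping[str, float]


def payer_adjust(cost_medicare: float, multiplier: float) -> float:
    """Scale a Medicare-schedule cost to the payer's reimbursement level."""
    if cost_medicare < 0:
        raise ValueError("cost must be >= 0")
    if multiplier < 1.0:
        raise ValueError("multiplier must be >= 1 (Medicare is the reference scale)")
    return cost_medicare * multiplier


def colonoscopy_episode_cost(
    params: ParameterSet,
    strategy: Strategy,
    p_adenoma: float | None = None,
) -> EpisodeCost:
    """Expected payer cost of one colonoscopy episode.

    Fee-schedule components (facility, physician, polypectomy increment,
    complication management, repeat exam) are scaled by the payer
    multiplier; the device is billed at list price.  ``p_adenoma`` is the
    adenoma prevalence in the examined population (screening prevalence by
    default; pass the surveillance recurrence prevalence for surveillance
    exams).
    """
    if p_adenoma is None:
        p_adenoma = params.p_adenoma_prevalence
    prof = episode_profile(params, strategy)
    m = params.payer_multiplier

    exam_unit = params.cost_colonoscopy_dx + params.cost_physician
    base_procedure = params.cost_colonoscopy_dx
    physician = params.cost_physician
    repeat_exam = prof.frac_repeat * exam_unit
    p_removal = p_adenoma * prof.p_detect_given_adenoma + (1.0 - p_adenoma) * prof.p_false_positive
    polypectomy = p_removal * params.cost_colonoscopy_polypectomy
    complication = prof.expected_exams * params.p_complication * params.cost_complication
    device = strategy.device_use_fraction * strategy.device_cost

    components = {
        "base_procedure": payer_adjust(base_procedure, m),
        "physician": payer_adjust(physician, m),
        "repeat_exam": payer_adjust(repeat_exam, m),
        "polypectomy_increment": payer_adjust(polypectomy, m),
        "complication": payer_adjust(complication, m),
        "device": device,
    }
    return EpisodeCost(expected_cost=sum(components.values()), components=components)
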