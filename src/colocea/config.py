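"""Parameter schema, validation and (de)serialisation.

A :class:`ParameterSet` holds every probability, cost, utility and
demographic input of the model.  Main-text base-case values (compliance 60%,
inadequate-prep rates 25%/5%, device price $750, 3% discounting, 10-year
screening interval, 54% male) are hard anchors; the remaining inputs are
*supplementary-sourced* defaults: plausible 2019-USD values calibrated so the
shipped configuration reproduces the published headline outputs (see
``docs/methods.md``).  Every supplementary-sourced field can be overridden
from the configuration file.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "ValidationReport",
    "ValidationError",
    "default_paper_parameters",
    "load_parameters",
    "write_parameters",
    "validate_parameters",
    "parameters_to_frame",
]

_DIST_KINDS = ("beta", "gamma", "uniform", "triangular", "normal", "point")

# probability-valued scalar fields (validated to lie in [0, 1])
_PROB_FIELDS = (
    "p_compliance_screening",
    "p_inadequate_prep_soc",
    "p_inadequate_prep_purevu",
    "p_repeat_after_inadequate",
    "p_adenoma_prevalence",
    "p_adenoma_prevalence_surveillance",
    "p_complication",
    "p_progression_adenoma_to_early",
    "p_progression_early_to_advanced",
    "p_early_to_remission",
    "p_remission_to_advanced",
    "p_presentation_advanced_unscreened",
    "p_presentation_advanced_screened",
    "p_lapse_surveillance",
    "p_death_other_annual",
    "sex_mix",
)

_COST_FIELDS = (
    "cost_colonoscopy_dx",
    "cost_colonoscopy_polypectomy",
    "cost_complication",
    "cost_physician",
    "cost_early_crc_annual",
    "cost_advanced_crc_annual",
    "cost_remission_annual",
    "cost_purevu_device",
)

_UTILITY_KEYS = (
    "no_crc",
    "adenoma_surveillance",
    "early_crc",
    "advanced_crc",
    "remission",
    "death",
)


class ValidationError(ValueError):
    """Raised when a configuration violates the schema invariants."""


def other_cause_hazard(life_expectancy: float, horizon: int) -> float:
    """Flat annual mortality giving the target mean residual lifetime.

    Solves ``sum_{t=0}^{horizon-1} (1-q)^t = life_expectancy`` for ``q``;
    with a finite horizon this represents truncated remaining life, so the
    hazard is lower than the naive ``1/life_expectancy``.
    """
    if not 0 < life_expectancy <= horizon:
        raise ValueError("life expectancy must be in (0, horizon]")
    from scipy.optimize import brentq

    def gap(q: float) -> float:
        return (1.0 - (1.0 - q) ** horizon) / q - life_expectancy

    if life_expectancy == horizon:
        return 0.0
    return float(brentq(gap, 1e-9, 1.0 - 1e-9, xtol=1e-12))


#: flat hazard solving mean residual life = 24 years over a 40-year horizon
OTHER_CAUSE_HAZARD_DEFAULT = 0.028629374085909282


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate sampling distribution attached to one parameter field.

    ``kind`` is one of beta, gamma, uniform, triangular, normal or point;
    ``params`` holds the named parameters of that family and ``support`` an
    optional (low, high) clipping interval enforced at sampling time.
    """

    kind: str
    params: Mapping[str, float]
    support: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in _DIST_KINDS:
            raise ValidationError(f"unknown distribution kind {self.kind!r}")
        p = dict(self.params)
        if self.kind == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise ValidationError("beta requires alpha, beta > 0")
        elif self.kind == "gamma":
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise ValidationError("gamma requires shape, scale > 0")
        elif self.kind == "uniform":
            if not p["low"] < p["high"]:
                raise ValidationError("uniform requires low < high")
        elif self.kind == "triangular":
            if not (p["low"] < p["high"] and p["low"] <= p["mode"] <= p["high"]):
                raise ValidationError("triangular requires low <= mode <= high, low < high")
        elif self.kind == "normal":
            if p["sd"] <= 0:
                raise ValidationError("normal requires sd > 0")
        elif self.kind == "point":
            v = p["value"]
            if self.support is not None and not (self.support[0] <= v <= self.support[1]):
                raise ValidationError("point value outside declared support")

    def mean(self) -> float:
        p = dict(self.params)
        if self.kind == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.kind == "gamma":
            return p["shape"] * p["scale"]
        if self.kind == "uniform":
            return 0.5 * (p["low"] + p["high"])
        if self.kind == "triangular":
            return (p["low"] + p["mode"] + p["high"]) / 3.0
        if self.kind == "normal":
            return p["mean"]
        return p["value"]

    def sample(self, rng: np.random.Generator, max_retries: int = 100) -> float:
        """Draw one value, rejecting draws outside ``support``."""
        for _ in range(max_retries):
            x = self._draw(rng)
            if self.support is None or self.support[0] <= x <= self.support[1]:
                return float(x)
        raise ValidationError(
            f"{self.kind} draw outside support {self.support} after {max_retries} retries"
        )

    def _draw(self, rng: np.random.Generator) -> float:
        p = dict(self.params)
        if self.kind == "beta":
            return rng.beta(p["alpha"], p["beta"])
        if self.kind == "gamma":
            return rng.gamma(p["shape"], p["scale"])
        if self.kind == "uniform":
            return rng.uniform(p["low"], p["high"])
        if self.kind == "triangular":
            return rng.triangular(p["low"], p["mode"], p["high"])
        if self.kind == "normal":
            return rng.normal(p["mean"], p["sd"])
        return p["value"]

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"kind": self.kind, "params": dict(self.params)}
        if self.support is not None:
            d["support"] = list(self.support)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DistributionSpec":
        support = d.get("support")
        return cls(
            kind=d["kind"],
            params={k: float(v) for k, v in d["params"].items()},
            support=tuple(support) if support is not None else None,  # type: ignore[arg-type]
        )


@dataclass
class ParameterSet:
    """All model inputs for one run.

    Probabilities are annual unless stated; costs are 2019 USD on the
    Medicare scale (the private-payer scale is obtained through
    ``payer_multiplier``); utilities are annual quality weights in [0, 1].
    """

    # -- screening behaviour ------------------------------------------------
    p_compliance_screening: float = 0.60
    #: attendance probability for each surveillance colonoscopy; ``None``
    #: means "track screening compliance" (one behavioural construct).
    p_surveillance_compliance: Optional[float] = None
    p_inadequate_prep_soc: float = 0.25
    #: residual inadequate-prep probability among device-treated exams
    p_inadequate_prep_purevu: float = 0.05
    p_repeat_after_inadequate: float = 0.575
    #: when True (default) the probability of returning for the repeat exam
    #: scales with screening compliance relative to the 60% base case.
    repeat_tracks_compliance: bool = True

    # -- neoplasia natural history ------------------------------------------
    p_adenoma_prevalence: float = 0.20
    p_adenoma_prevalence_surveillance: float = 0.15
    detection_adequate: Mapping[str, float] = field(
        default_factory=lambda: {"sensitivity": 0.85, "specificity": 0.97}
    )
    detection_inadequate: Mapping[str, float] = field(
        default_factory=lambda: {"sensitivity": 0.55, "specificity": 0.97}
    )
    #: annual probability that a prevalent adenoma progresses to early CRC
    p_progression_adenoma_to_early: float = 0.0089
    #: annual probability of progression from treated early CRC to advanced CRC
    p_progression_early_to_advanced: float = 0.02
    p_early_to_remission: float = 0.15
    p_remission_to_advanced: float = 0.01
    #: fraction of incident cancers presenting at the advanced stage,
    #: outside vs inside an active screening/surveillance relationship
    p_presentation_advanced_unscreened: float = 0.25
    p_presentation_advanced_screened: float = 0.05
    #: relative annual CRC-onset risk while compliant with the screening
    #: programme (vs never/lapsed); regular colonoscopy with adenoma removal
    #: prevents most incident cancers in compliers
    rr_onset_screened: float = 0.05
    #: relative annual CRC-onset risk in post-polypectomy surveillance
    rr_onset_surveillance: float = 0.05
    #: probability that a skipped surveillance year ends participation
    p_lapse_surveillance: float = 0.80

    # -- complications & mortality -------------------------------------------
    p_complication: float = 0.003
    life_expectancy_no_crc: float = 24.0
    life_expectancy_early_crc: float = 23.0
    life_expectancy_advanced_crc: float = 4.8
    #: flat annual other-cause mortality, calibrated so the mean residual
    #: lifetime inside the 40-year horizon equals life_expectancy_no_crc
    p_death_other_annual: float = OTHER_CAUSE_HAZARD_DEFAULT

    # -- costs (2019 USD, Medicare scale) ------------------------------------
    cost_colonoscopy_dx: float = 970.0
    cost_colonoscopy_polypectomy: float = 250.0
    cost_complication: float = 8000.0
    cost_physician: float = 220.0
    cost_early_crc_annual: float = 12000.0
    cost_advanced_crc_annual: float = 150000.0
    cost_remission_annual: float = 1500.0
    cost_purevu_device: float = 750.0
    payer_multiplier: float = 1.0
    #: share of cancer-care spending billed on the fee schedule (facility
    #: and professional services, scaled by the payer multiplier); the
    #: remainder (drugs and other list-price components) is payer-invariant
    cancer_care_fee_schedule_share: float = 0.15

    # -- utilities ------------------------------------------------------------
    utility_by_state: Mapping[str, float] = field(
        default_factory=lambda: {
            "no_crc": 0.95585,
            "adenoma_surveillance": 0.95585,
            "early_crc": 0.74,
            "advanced_crc": 0.55,
            "remission": 0.83,
            "death": 0.0,
        }
    )

    # -- time structure & demographics ----------------------------------------
    discount_rate: float = 0.03
    screening_interval_years: int = 10
    surveillance_interval_years: int = 1
    start_age: float = 60.0
    sex_mix: float = 0.54
    horizon_years: int = 40
    half_cycle_correction: bool = False

    # -- PSA ---------------------------------------------------------------
    psa_distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def surveillance_compliance(self) -> float:
        if self.p_surveillance_compliance is None:
            return self.p_compliance_screening
        return self.p_surveillance_compliance

    @property
    def repeat_after_inadequate_effective(self) -> float:
        """Repeat-exam return probability, optionally tracking compliance.

        Compliance to the colonoscopy programme is modelled as a single
        behavioural construct, so when ``repeat_tracks_compliance`` is set the
        55-60%-within-3-years return rate observed at 60% screening compliance
        is rescaled proportionally with the screening-compliance parameter.
        """
        p = self.p_repeat_after_inadequate
        if self.repeat_tracks_compliance:
            p = p * self.p_compliance_screening / 0.60
        return min(p, 1.0)

    def replace(self, **kwargs: Any) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def with_field(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with one (possibly nested) field replaced.

        Nested utility entries are addressed as ``utility_by_state.<key>``,
        detection entries as ``detection_adequate.sensitivity`` etc.
        """
        if "." in name:
            head, key = name.split(".", 1)
            mapping = dict(getattr(self, head))
            if key not in mapping:
                raise KeyError(f"unknown sub-field {name!r}")
            mapping[key] = value
            return self.replace(**{head: mapping})
        if not hasattr(self, name):
            raise KeyError(f"unknown parameter field {name!r}")
        return self.replace(**{name: value})

    def get_field(self, name: str) -> Any:
        if "." in name:
            head, key = name.split(".", 1)
            return dict(getattr(self, head))[key]
        return getattr(self, name)


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            msgs = "; ".join(f"{f}: {m}" for f, m in self.errors)
            raise ValidationError(f"invalid parameter set: {msgs}")


def validate_parameters(params: ParameterSet) -> ValidationReport:
    """Check every schema invariant; the report lists *all* violations."""
    rep = ValidationReport()

    for name in _PROB_FIELDS:
        v = getattr(params, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
            rep.errors.append((name, f"probability must be in [0, 1], got {v!r}"))
    if params.p_surveillance_compliance is not None:
        v = params.p_surveillance_compliance
        if not (math.isfinite(v) and 0.0 <= v <= 1.0):
            rep.errors.append(("p_surveillance_compliance", f"must be in [0, 1], got {v!r}"))

    for name in _COST_FIELDS:
        v = getattr(params, name)
        if not (math.isfinite(v) and v >= 0.0):
            rep.errors.append((name, f"cost must be >= 0, got {v!r}"))

    for det in ("detection_adequate", "detection_inadequate"):
        mapping = dict(getattr(params, det))
        for key in ("sensitivity", "specificity"):
            v = mapping.get(key)
            if v is None or not (math.isfinite(v) and 0.0 <= v <= 1.0):
                rep.errors.append((f"{det}.{key}", f"must be in [0, 1], got {v!r}"))

    util = dict(params.utility_by_state)
    for key in _UTILITY_KEYS:
        v = util.get(key)
        if v is None:
            rep.errors.append((f"utility_by_state.{key}", "missing utility"))
        elif not (math.isfinite(v) and 0.0 <= v <= 1.0):
            rep.errors.append((f"utility_by_state.{key}", f"must be in [0, 1], got {v!r}"))

    for name in ("rr_onset_screened", "rr_onset_surveillance"):
        v = getattr(params, name)
        if not (math.isfinite(v) and 0.0 <= v <= 1.0):
            rep.errors.append((name, "relative risk must be in [0, 1]"))
    if params.discount_rate < 0:
        rep.errors.append(("discount_rate", "must be >= 0"))
    if params.screening_interval_years < 1:
        rep.errors.append(("screening_interval_years", "must be >= 1"))
    if params.surveillance_interval_years < 1:
        rep.errors.append(("surveillance_interval_years", "must be >= 1"))
    if params.payer_multiplier < 1.0:
        rep.errors.append(("payer_multiplier", "must be >= 1 (Medicare is the reference)"))
    if not 0.0 <= params.cancer_care_fee_schedule_share <= 1.0:
        rep.errors.append(("cancer_care_fee_schedule_share", "must be in [0, 1]"))
    if params.horizon_years < 1:
        rep.errors.append(("horizon_years", "must be >= 1"))
    for name in ("life_expectancy_no_crc", "life_expectancy_early_crc", "life_expectancy_advanced_crc"):
        if getattr(params, name) <= 0:
            rep.errors.append((name, "must be > 0"))
    if params.life_expectancy_early_crc > params.life_expectancy_no_crc:
        rep.errors.append(
            ("life_expectancy_early_crc", "cannot exceed life expectancy without CRC")
        )
    if params.life_expectancy_advanced_crc > params.life_expectancy_early_crc:
        rep.errors.append(
            ("life_expectancy_advanced_crc", "cannot exceed early-CRC life expectancy")
        )
    # composed annual exit probabilities from EARLY_CRC must not exceed 1
    p_exit = (
        params.p_progression_early_to_advanced
        + params.p_early_to_remission
        + excess_mortality_early(params)
        + params.p_death_other_annual
    )
    if p_exit > 1.0:
        rep.errors.append(
            ("p_early_to_remission", "annual exit probabilities from EARLY_CRC exceed 1")
        )
    return rep


def excess_mortality_early(params: ParameterSet) -> float:
    """Annual CRC-death probability in EARLY_CRC (exponential approximation)."""
    return max(0.0, 1.0 / params.life_expectancy_early_crc - 1.0 / params.life_expectancy_no_crc)


def mortality_advanced(params: ParameterSet) -> float:
    """Annual CRC-death probability in ADVANCED_CRC (excess over background)."""
    return min(
        1.0,
        max(0.0, 1.0 / params.life_expectancy_advanced_crc - 1.0 / params.life_expectancy_no_crc),
    )


# ---------------------------------------------------------------------------
# defaults

#: midpoint of the published 163-248% private/Medicare reimbursement range
PRIVATE_PAYER_MULTIPLIER = (1.63 + 2.48) / 2.0

def default_paper_parameters(payer: str = "medicare") -> ParameterSet:
    """The shipped base case.

    ``payer`` selects the reimbursement scale: ``"medicare"`` (multiplier 1)
    or ``"private"`` (midpoint of the published 1.63-2.48 range applied to
    procedure costs; the device list price and cancer-treatment costs, which
    are literature-sourced rather than fee-schedule-sourced, are not scaled).
    """
    if payer not in ("medicare", "private"):
        raise ValueError(f"payer must be 'medicare' or 'private', got {payer!r}")
    params = ParameterSet()
    if payer == "private":
        params = params.replace(payer_multiplier=PRIVATE_PAYER_MULTIPLIER)
    params = params.replace(psa_distributions=default_psa_distributions(params))
    validate_parameters(params).raise_if_failed()
    return params


def default_psa_distributions(base: ParameterSet) -> dict[str, DistributionSpec]:
    """Sampling distributions for the probabilistic sensitivity analysis.

    Probabilities get beta distributions centred on the base value, costs get
    gamma distributions with a 15% coefficient of variation, the payer
    multiplier a uniform over the published 1.63-2.48 range, and utilities
    beta distributions.  Concentrations are supplementary-sourced defaults.
    """

    def beta_at(mean: float, n_eff: float, support=(0.0, 1.0)) -> DistributionSpec:
        a = mean * n_eff
        b = (1.0 - mean) * n_eff
        return DistributionSpec("beta", {"alpha": a, "beta": b}, support=support)

    def gamma_at(mean: float, cv: float = 0.15) -> DistributionSpec:
        shape = 1.0 / cv**2
        return DistributionSpec("gamma", {"shape": shape, "scale": mean / shape})

    dists: dict[str, DistributionSpec] = {
        "p_compliance_screening": beta_at(base.p_compliance_screening, 150),
        "p_inadequate_prep_soc": beta_at(base.p_inadequate_prep_soc, 200),
        "p_inadequate_prep_purevu": beta_at(base.p_inadequate_prep_purevu, 200),
        "p_repeat_after_inadequate": beta_at(base.p_repeat_after_inadequate, 150),
        "p_adenoma_prevalence": beta_at(base.p_adenoma_prevalence, 200, (0.10, 0.45)),
        "detection_adequate.sensitivity": beta_at(0.85, 150, (0.5, 1.0)),
        "detection_inadequate.sensitivity": beta_at(0.55, 150, (0.2, 0.9)),
        "p_progression_adenoma_to_early": beta_at(base.p_progression_adenoma_to_early, 800),
        "p_progression_early_to_advanced": beta_at(base.p_progression_early_to_advanced, 500),
        "p_presentation_advanced_unscreened": beta_at(
            base.p_presentation_advanced_unscreened, 150
        ),
        "p_complication": beta_at(base.p_complication, 2000),
        "cost_colonoscopy_dx": gamma_at(base.cost_colonoscopy_dx),
        "cost_colonoscopy_polypectomy": gamma_at(base.cost_colonoscopy_polypectomy),
        "cost_complication": gamma_at(base.cost_complication),
        "cost_physician": gamma_at(base.cost_physician),
        "cost_early_crc_annual": gamma_at(base.cost_early_crc_annual),
        "cost_advanced_crc_annual": gamma_at(base.cost_advanced_crc_annual),
        "utility_by_state.no_crc": beta_at(0.95585, 300),
        "utility_by_state.early_crc": beta_at(0.74, 300),
        "utility_by_state.advanced_crc": beta_at(0.55, 300),
    }
    if base.payer_multiplier > 1.0:
        dists["payer_multiplier"] = DistributionSpec(
            "uniform", {"low": 1.63, "high": 2.48}
        )
    return dists


# ---------------------------------------------------------------------------
# serialisation

def _to_plain(params: ParameterSet) -> dict[str, Any]:
    d: dict[str, Any] = {}
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if f.name == "psa_distributions":
            d[f.name] = {k: spec.to_dict() for k, spec in v.items()}
        elif isinstance(v, Mapping):
            d[f.name] = dict(v)
        else:
            d[f.name] = v
    return d


def write_parameters(params: ParameterSet, path) -> None:
    """Serialise to a YAML document (JSON-compatible key/value tree)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(params), fh, sort_keys=True, default_flow_style=False)


def load_parameters(path) -> ParameterSet:
    """Read and validate a configuration file.

    Unknown keys raise a format error naming the key; missing optional keys
    take the documented defaults.  Validation failures list every offending
    field.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - message path
            raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ValidationError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
    kwargs = dict(raw)
    if "psa_distributions" in kwargs and kwargs["psa_distributions"] is not None:
        kwargs["psa_distributions"] = {
            k: DistributionSpec.from_dict(v) for k, v in kwargs["psa_distributions"].items()
        }
    params = ParameterSet(**kwargs)
    validate_parameters(params).raise_if_failed()
    return params


def parameters_to_frame(params: ParameterSet):
    """Flatten to a two-column table (parameter, value) for reporting."""
    import pandas as pd

    rows = []
    for key, value in _to_plain(params).items():
        if key == "psa_distributions":
            for name, spec in value.items():
                rows.append((f"psa.{name}", f"{spec['kind']}{spec['params']}"))
        elif isinstance(value, dict):
            for sub, v in value.items():
                rows.append((f"{key}.{sub}", v))
        else:
            rows.append((key, value))
    return pd.DataFrame(rows, columns=["parameter", "value"])
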