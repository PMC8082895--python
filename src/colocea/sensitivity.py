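"""One-way sensitivity sweeps and bisection threshold finding.

A sweep re-runs both arms over a grid of values for one parameter with
everything else at base case.  A threshold search bisects on the sign of
the deterministic lifetime-cost difference (standard of care minus
intervention): the threshold is the parameter value at which the cheaper
strategy flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .config import ParameterSet, validate_parameters
from .engine import run_arm
from .strategies import PUREVU, SOC, make_strategy

__all__ = ["SweepResult", "ThresholdResult", "one_way_sweep", "find_threshold", "NoCrossingError"]


class NoCrossingError(ValueError):
    """The cost-difference predicate has the same sign at both bracket ends."""


@dataclass(frozen=True)
class SweepPoint:
    value: float
    soc_cost: float
    soc_qaly: float
    purevu_cost: float
    purevu_qaly: float

    @property
    def saving(self) -> float:
        return self.soc_cost - self.purevu_cost

    @property
    def cost_per_qaly_saving(self) -> float:
        """Difference of the per-arm average cost/QALY ratios."""
        return self.soc_cost / self.soc_qaly - self.purevu_cost / self.purevu_qaly


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    points: tuple[SweepPoint, ...]

    @property
    def grid(self) -> tuple[float, ...]:
        return tuple(p.value for p in self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.parameter: self.grid,
                "soc_cost": [p.soc_cost for p in self.points],
                "soc_qaly": [p.soc_qaly for p in self.points],
                "purevu_cost": [p.purevu_cost for p in self.points],
                "purevu_qaly": [p.purevu_qaly for p in self.points],
                "saving": [p.saving for p in self.points],
                "cost_per_qaly_saving": [p.cost_per_qaly_saving for p in self.points],
            }
        )


def _paired_costs(params: ParameterSet) -> SweepPoint:
    soc = run_arm(params, make_strategy(SOC, payer_of(params), params), validate=False)
    pv = run_arm(params, make_strategy(PUREVU, payer_of(params), params), validate=False)
    return SweepPoint(
        value=float("nan"),
        soc_cost=soc.total_cost,
        soc_qaly=soc.total_qaly,
        purevu_cost=pv.total_cost,
        purevu_qaly=pv.total_qaly,
    )


def payer_of(params: ParameterSet) -> str:
    return "medicare" if params.payer_multiplier == 1.0 else "private"


def one_way_sweep(params: ParameterSet, parameter: str, grid: Sequence[float]) -> SweepResult:
    """Re-run both arms at each grid value of ``parameter``; grid is sorted."""
    values = sorted(float(v) for v in grid)
    points = []
    for v in values:
        p = params.with_field(parameter, v)
        rep = validate_parameters(p)
        if not rep.ok:
            raise ValueError(f"invalid grid value {v!r} for {parameter}: {rep.errors}")
        pt = _paired_costs(p)
        points.append(
            SweepPoint(v, pt.soc_cost, pt.soc_qaly, pt.purevu_cost, pt.purevu_qaly)
        )
    return SweepResult(parameter=parameter, points=tuple(points))


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    threshold: float
    bracket: tuple[float, float]
    tolerance: float
    predicate: str


def cost_difference(params: ParameterSet, parameter: str, value: float) -> float:
    """SOC lifetime cost minus PureVu lifetime cost at one parameter value."""
    p = params.with_field(parameter, value)
    pt = _paired_costs(p)
    return pt.saving


def find_threshold(
    params: ParameterSet,
    parameter: str,
    bracket: tuple[float, float],
    tol: float,
    objective: Callable[[ParameterSet, str, float], float] = cost_difference,
) -> ThresholdResult:
    """Bisect the sign change of the cost difference over ``bracket``.

    Deterministic: pure bisection until the bracket width is <= ``tol``;
    the threshold is the final bracket midpoint.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy low < high")
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    f_lo = objective(params, parameter, lo)
    f_hi = objective(params, parameter, hi)
    if f_lo == 0.0:
        return ThresholdResult(parameter, lo, (lo, lo), 0.0, "soc_cost - purevu_cost")
    if f_hi == 0.0:
        return ThresholdResult(parameter, hi, (hi, hi), 0.0, "soc_cost - purevu_cost")
    if (f_lo > 0) == (f_hi > 0):
        raise NoCrossingError(
            f"cost difference has the same sign at both ends of {bracket} for {parameter}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = objective(params, parameter, mid)
        if f_mid == 0.0:
            lo = hi = mid
            break
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return ThresholdResult(
        parameter=parameter,
        threshold=0.5 * (lo + hi),
        bracket=(lo, hi),
        tolerance=hi - lo,
        predicate="soc_cost - purevu_cost",
    )
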