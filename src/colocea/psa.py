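"""Probabilistic sensitivity analysis.

Parameters carrying a :class:`~colocea.config.DistributionSpec` are drawn
independently; both strategy arms are evaluated on the *same* sampled
parameter set (common random parameters), so each draw yields one point on
the cost-effectiveness plane.  Convergence of the running mean ICER is
monitored with a trailing-window rule: the analysis is declared converged at
the first draw after which the running mean never again moves by more than a
relative tolerance (0.1% by default) within the look-ahead window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ParameterSet, validate_parameters
from .engine import run_arm
from .strategies import PUREVU, SOC, make_strategy

__all__ = ["PSASample", "PSAResult", "sample_parameters", "run_psa", "summarize_ce_plane"]

#: draws with |delta QALY| below this are excluded from the ICER running mean
ICER_DQ_EPS = 1e-9


def sample_parameters(base: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One random parameter set: distributed fields re-drawn, others kept."""
    sampled = base
    for name, spec in base.psa_distributions.items():
        sampled = sampled.with_field(name, spec.sample(rng))
    rep = validate_parameters(sampled)
    if not rep.ok:
        rep.raise_if_failed()
    return sampled


@dataclass(frozen=True)
class PSASample:
    draw_index: int
    soc_cost: float
    soc_qaly: float
    purevu_cost: float
    purevu_qaly: float
    inb_at_wtp: float

    @property
    def delta_cost(self) -> float:
        return self.purevu_cost - self.soc_cost

    @property
    def delta_qaly(self) -> float:
        return self.purevu_qaly - self.soc_qaly


@dataclass
class PSAResult:
    samples: list[PSASample]
    mean_icer_trajectory: np.ndarray
    converged_at: Optional[int]
    inb_mean: float
    inb_ci95: tuple[float, float]
    prob_positive_inb: float
    n_excluded_icer: int
    wtp: float
    seed: Optional[int]

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": [s.draw_index for s in self.samples],
                "soc_cost": [s.soc_cost for s in self.samples],
                "soc_qaly": [s.soc_qaly for s in self.samples],
                "purevu_cost": [s.purevu_cost for s in self.samples],
                "purevu_qaly": [s.purevu_qaly for s in self.samples],
                "delta_cost": [s.delta_cost for s in self.samples],
                "delta_qaly": [s.delta_qaly for s in self.samples],
                "inb": [s.inb_at_wtp for s in self.samples],
                "running_mean_icer": self.mean_icer_trajectory,
            }
        )


def _converged_at(traj: np.ndarray, tol: float, window: int) -> Optional[int]:
    """First draw index k >= 2 with |RM_j - RM_k| <= tol |RM_k| for the
    next ``window`` draws (and through the end of the trajectory)."""
    n = len(traj)
    for k in range(1, n):  # 0-based position; draw number k+1 >= 2
        rk = traj[k]
        if not np.isfinite(rk) or rk == 0.0:
            continue
        end = min(n, k + 1 + window)
        if end - (k + 1) <= 0:
            break
        seg = traj[k + 1 : end]
        if np.all(np.abs(seg - rk) <= tol * abs(rk)):
            return k + 1  # report as draw count (1-based)
    return None


def run_psa(
    base: ParameterSet,
    n_max: int = 10_000,
    convergence_tol: float = 0.001,
    seed: Optional[int] = None,
    wtp: float = 50_000.0,
    window: int = 100,
    payer: Optional[str] = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Returns paired arm outcomes per draw, the running-mean-ICER trajectory,
    the convergence draw (``None`` if the tolerance is never held over the
    trailing window), and incremental-net-benefit summaries at ``wtp``.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if convergence_tol <= 0:
        raise ValueError("convergence tolerance must be > 0")
    if payer is None:
        payer = "medicare" if base.payer_multiplier == 1.0 else "private"

    streams = np.random.SeedSequence(seed).spawn(n_max)
    samples: list[PSASample] = []
    traj = np.full(n_max, np.nan)
    icer_sum = 0.0
    icer_n = 0
    excluded = 0

    for i in range(n_max):
        rng = np.random.default_rng(streams[i])
        params = sample_parameters(base, rng)
        soc = run_arm(params, make_strategy(SOC, payer, params), validate=False)
        pv = run_arm(params, make_strategy(PUREVU, payer, params), validate=False)
        dc = pv.total_cost - soc.total_cost
        dq = pv.total_qaly - soc.total_qaly
        inb = wtp * dq - dc
        samples.append(
            PSASample(
                draw_index=i,
                soc_cost=soc.total_cost,
                soc_qaly=soc.total_qaly,
                purevu_cost=pv.total_cost,
                purevu_qaly=pv.total_qaly,
                inb_at_wtp=inb,
            )
        )
        if abs(dq) >= ICER_DQ_EPS:
            icer_sum += dc / dq
            icer_n += 1
        else:
            excluded += 1
        traj[i] = icer_sum / icer_n if icer_n else np.nan

    inbs = np.array([s.inb_at_wtp for s in samples])
    lo, hi = np.percentile(inbs, [2.5, 97.5])
    return PSAResult(
        samples=samples,
        mean_icer_trajectory=traj,
        converged_at=_converged_at(traj, convergence_tol, window),
        inb_mean=float(inbs.mean()),
        inb_ci95=(float(lo), float(hi)),
        prob_positive_inb=float((inbs > 0).mean()),
        n_excluded_icer=excluded,
        wtp=wtp,
        seed=seed,
    )


@dataclass(frozen=True)
class CEPlaneSummary:
    quadrant_fractions: dict[str, float]
    inb_mean: float
    inb_ci95: tuple[float, float]
    prob_positive_inb: float
    n: int


def summarize_ce_plane(result: PSAResult, wtp: float) -> CEPlaneSummary:
    """Quadrant shares and INB summary of the cost-effectiveness plane."""
    if result.n_draws < 2:
        raise ValueError("need at least 2 PSA samples to summarise")
    dc = np.array([s.delta_cost for s in result.samples])
    dq = np.array([s.delta_qaly for s in result.samples])
    inb = wtp * dq - dc
    quadrants = {
        "cheaper_more_effective": float(((dc <= 0) & (dq >= 0)).mean()),
        "costlier_more_effective": float(((dc > 0) & (dq >= 0)).mean()),
        "cheaper_less_effective": float(((dc <= 0) & (dq < 0)).mean()),
        "costlier_less_effective": float(((dc > 0) & (dq < 0)).mean()),
    }
    lo, hi = np.percentile(inb, [2.5, 97.5])
    return CEPlaneSummary(
        quadrant_fractions=quadrants,
        inb_mean=float(inb.mean()),
        inb_ci95=(float(lo), float(hi)),
        prob_positive_inb=float((inb > 0).mean()),
        n=result.n_draws,
    )
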