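"""Logistic modelling and propensity-score matching of colonoscopy studies.

Two uses of the same logistic machinery, mirroring how observational
colonoscopy data are balanced before feeding a decision model:

* an *outcome* model — successful colonoscopy ~ age + sex + device use +
  cecal intubation — reported with Wald tests to identify significant
  predictors;
* a *treatment* model — device use ~ age + sex — whose fitted probabilities
  are the propensity scores used for greedy 1:1 caliper matching.

The maximum-likelihood fit is iteratively reweighted least squares (IRLS)
with a log-likelihood convergence tolerance of 1e-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "PropensityModel",
    "MatchedSet",
    "SeparationError",
    "DegenerateDataError",
    "fit_logistic",
    "score",
    "match",
    "balance_check",
    "records_to_frame",
]

OUTCOME_COVARIATES = ("age", "sex", "device_used", "cecal_intubation")
TREATMENT_COVARIATES = ("age", "sex")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: coefficients diverge."""


class DegenerateDataError(ValueError):
    """The outcome is constant (or the design is otherwise degenerate)."""


@dataclass(frozen=True)
class StudyRecord:
    age: float
    sex: int  # 1 = male, 0 = female
    device_used: int
    cecal_intubation: float  # depth of insertion reached, 0-1 scale
    success: int

    def __post_init__(self) -> None:
        if self.sex not in (0, 1) or self.device_used not in (0, 1) or self.success not in (0, 1):
            raise ValueError("sex, device_used and success must be binary (0/1)")
        if not 0.0 <= self.cecal_intubation <= 1.0:
            raise ValueError("cecal_intubation must be in [0, 1]")


def records_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "device_used": [r.device_used for r in records],
            "cecal_intubation": [r.cecal_intubation for r in records],
            "success": [r.success for r in records],
        }
    )


@dataclass
class PropensityModel:
    covariate_names: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    converged: bool
    n_iter: int
    log_likelihood: float
    standard_errors: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        beta = np.array([self.coefficients[c] for c in self.covariate_names])
        return self.intercept + X @ beta

    def wald_table(self) -> pd.DataFrame:
        """Coefficients, standard errors, z statistics and two-sided p-values."""
        from scipy.stats import norm

        rows = []
        for name in ("(intercept)",) + self.covariate_names:
            est = self.intercept if name == "(intercept)" else self.coefficients[name]
            se = self.standard_errors.get(name, float("nan"))
            z = est / se if se and math.isfinite(se) and se > 0 else float("nan")
            p = 2 * norm.sf(abs(z)) if math.isfinite(z) else float("nan")
            rows.append((name, est, se, z, p))
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "z", "p_value"])


def _design(records: Sequence[StudyRecord], covariates: Sequence[str], outcome: str) -> tuple[np.ndarray, np.ndarray]:
    df = records_to_frame(records)
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"unknown covariate(s): {missing}")
    return df[list(covariates)].to_numpy(float), df[outcome].to_numpy(float)


def fit_logistic(
    records: Sequence[StudyRecord],
    covariates: Sequence[str] = OUTCOME_COVARIATES,
    outcome: str = "success",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PropensityModel:
    """Maximum-likelihood logit fit via IRLS.

    Raises :class:`DegenerateDataError` for a constant outcome and
    :class:`SeparationError` when the likelihood keeps improving with
    diverging coefficients (complete separation).
    """
    if len(records) < 10:
        raise DegenerateDataError("need at least 10 records to fit")
    X, y = _design(records, covariates, outcome)
    if y.min() == y.max():
        raise DegenerateDataError("outcome is constant; logistic model is not identified")

    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    ll_old = -np.inf
    cov = None
    for it in range(1, max_iter + 1):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError("coefficients diverging; data are separable")
        WX = Xd * w[:, None]
        H = Xd.T @ WX
        g = Xd.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix (separation or collinearity)") from exc
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol:
            cov = np.linalg.inv(H)
            break
        ll_old = ll
    else:
        raise SeparationError(f"IRLS did not converge in {max_iter} iterations")

    se = np.sqrt(np.diag(cov))
    names = tuple(covariates)
    return PropensityModel(
        covariate_names=names,
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(names, beta[1:])},
        converged=True,
        n_iter=it,
        log_likelihood=ll,
        standard_errors={"(intercept)": float(se[0]), **{c: float(s) for c, s in zip(names, se[1:])}},
    )


def score(model: PropensityModel, records: Sequence[StudyRecord]) -> np.ndarray:
    """Fitted probabilities (inverse-logit of the linear predictor)."""
    if not model.converged:
        raise ValueError("model did not converge; scores are not reliable")
    X, _ = _design(records, model.covariate_names, "success")
    eta = np.clip(model.linear_predictor(X), -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class MatchedSet:
    pairs: tuple[tuple[int, int], ...]  # (treated index, control index)
    caliper: float
    unmatched_treated: int


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, float), 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def match(
    scores_treated: Iterable[float],
    scores_control: Iterable[float],
    caliper: float | None = None,
) -> MatchedSet:
    """Greedy nearest-neighbour 1:1 matching on the logit of the score.

    Treated units are processed in descending score order; each takes the
    closest unused control within the caliper.  The default caliper is 0.2
    standard deviations of the pooled logit scores (common convention).
    """
    lt = _logit(list(scores_treated))
    lc = _logit(list(scores_control))
    if caliper is None:
        pooled = np.concatenate([lt, lc])
        caliper = 0.2 * float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.2
        caliper = caliper if caliper > 0 else 0.2
    if caliper <= 0:
        raise ValueError("caliper must be > 0")

    order = np.argsort(-lt, kind="stable")
    available = np.ones(len(lc), dtype=bool)
    pairs: list[tuple[int, int]] = []
    unmatched = 0
    for ti in order:
        if not available.any():
            unmatched += 1
            continue
        dist = np.abs(lc - lt[ti])
        dist[~available] = np.inf
        ci = int(np.argmin(dist))
        if dist[ci] <= caliper:
            pairs.append((int(ti), ci))
            available[ci] = False
        else:
            unmatched += 1
    return MatchedSet(pairs=tuple(pairs), caliper=float(caliper), unmatched_treated=unmatched)


def balance_check(
    treated: Sequence[StudyRecord],
    control: Sequence[StudyRecord],
    matched: MatchedSet,
    covariates: Sequence[str] = TREATMENT_COVARIATES,
) -> pd.DataFrame:
    """Standardised mean differences over the matched pairs.

    SMD = (mean_treated − mean_control) / pooled SD; a zero pooled SD is
    reported as SMD 0 with ``degenerate`` flagged.
    """
    if not matched.pairs:
        raise ValueError("need at least one matched pair")
    ti = [t for t, _ in matched.pairs]
    ci = [c for _, c in matched.pairs]
    df_t = records_to_frame([treated[i] for i in ti])
    df_c = records_to_frame([control[i] for i in ci])
    rows = []
    for cov in covariates:
        xt, xc = df_t[cov].to_numpy(float), df_c[cov].to_numpy(float)
        pooled = math.sqrt(0.5 * (xt.var(ddof=1) + xc.var(ddof=1))) if len(xt) > 1 else 0.0
        if pooled == 0.0:
            rows.append((cov, 0.0, True))
        else:
            rows.append((cov, float((xt.mean() - xc.mean()) / pooled), False))
    return pd.DataFrame(rows, columns=["covariate", "smd", "degenerate"])
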