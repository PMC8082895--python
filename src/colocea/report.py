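"""Report writers: CSV/JSON outputs mirroring the published tables.

Every entry point writes its outputs plus a ``manifest.json`` recording the
command, configuration, seed, package version and output paths, so any run
can be reproduced byte for byte from its manifest.  All rounding happens at
the reporting boundary; computations keep full precision.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cea import compare, cost_per_qaly
from .config import ParameterSet, default_paper_parameters, load_parameters, parameters_to_frame
from .engine import accrue_outcomes, run_arm, run_cohort, trace_to_frame
from .propensity import (
    OUTCOME_COVARIATES,
    TREATMENT_COVARIATES,
    balance_check,
    fit_logistic,
    match,
    score,
)
from .psa import run_psa, summarize_ce_plane
from .sensitivity import NoCrossingError, find_threshold, one_way_sweep
from .strategies import PUREVU, SOC, make_strategy
from .synth import SyntheticStudySpec, generate_study, occupancy_frequencies, simulate_patients
from .states import HealthState

__all__ = [
    "RunManifest",
    "resolve_parameters",
    "run_base_case",
    "run_sweep",
    "run_threshold",
    "run_psa_report",
    "run_propensity_report",
    "run_simulate",
]


@dataclass
class RunManifest:
    command: str
    config: Optional[str]
    seed: Optional[int]
    package_version: str = _version
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    outputs: list[str] = field(default_factory=list)

    def write(self, out_dir: Path) -> Path:
        """Write atomically (temp file + rename) alongside the outputs."""
        path = out_dir / "manifest.json"
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".manifest.tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        finally:
            if os.path.exists(tmp):  # pragma: no cover - cleanup path
                os.unlink(tmp)
        return path


def resolve_parameters(config: Optional[str], payer: str = "medicare") -> ParameterSet:
    """Load a configuration file, or fall back to the shipped base case."""
    if config is None:
        return default_paper_parameters(payer)
    params = load_parameters(config)
    if payer == "private" and params.payer_multiplier == 1.0:
        params = params.replace(payer_multiplier=default_paper_parameters("private").payer_multiplier)
    return params


def _prep(out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_base_case(config: Optional[str], out_dir, payers: Sequence[str] = ("medicare", "private")) -> Path:
    """All arm x payer combinations: lifetime table + per-arm stage traces."""
    out = _prep(out_dir)
    manifest = RunManifest(command="base-case", config=config, seed=None)
    rows = []
    for payer in payers:
        params = resolve_parameters(config, payer)
        results = {}
        for arm in (SOC, PUREVU):
            strategy = make_strategy(arm, payer, params)
            trace = run_cohort(params, strategy)
            res = accrue_outcomes(trace, params, strategy)
            results[arm] = res
            trace_path = out / f"trace_{arm}_{payer}.csv"
            trace_to_frame(trace).to_csv(trace_path, index=False)
            manifest.outputs.append(str(trace_path))
            rows.append(
                {
                    "payer": payer,
                    "arm": arm,
                    "cost": round(res.total_cost),
                    "qaly": round(res.total_qaly, 2),
                    "cost_per_qaly": cost_per_qaly(res.total_cost, res.total_qaly),
                    "cum_incidence_early_crc": round(res.cum_incidence_early_crc, 4),
                    "cum_incidence_advanced_crc": round(res.cum_incidence_advanced_crc, 4),
                }
            )
        inc = compare(results[PUREVU], results[SOC])
        rows.append(
            {
                "payer": payer,
                "arm": "purevu_vs_soc",
                "cost": round(inc.delta_cost),
                "qaly": round(inc.delta_qaly, 2),
                "cost_per_qaly": "" if inc.icer is None else round(inc.icer),
                "cum_incidence_early_crc": "",
                "cum_incidence_advanced_crc": "",
            }
        )
    table_path = out / "base_case.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)
    manifest.outputs.append(str(table_path))
    params_path = out / "parameters_flat.csv"
    parameters_to_frame(resolve_parameters(config, payers[0])).to_csv(params_path, index=False)
    manifest.outputs.append(str(params_path))
    manifest.write(out)
    return table_path


def run_sweep(
    config: Optional[str],
    parameter: str,
    grid: Sequence[float],
    out_dir,
    payer: str = "private",
) -> Path:
    out = _prep(out_dir)
    params = resolve_parameters(config, payer)
    sweep = one_way_sweep(params, parameter, grid)
    df = sweep.to_frame()
    df["soc_cost_per_qaly"] = (df["soc_cost"] / df["soc_qaly"]).round()
    df["purevu_cost_per_qaly"] = (df["purevu_cost"] / df["purevu_qaly"]).round()
    path = out / f"sweep_{parameter.replace('.', '_')}_{payer}.csv"
    df.round({"soc_cost": 0, "purevu_cost": 0, "soc_qaly": 2, "purevu_qaly": 2,
              "saving": 0, "cost_per_qaly_saving": 0}).to_csv(path, index=False)
    manifest = RunManifest(command=f"sweep {parameter}", config=config, seed=None, outputs=[str(path)])
    manifest.write(out)
    return path


def run_threshold(
    config: Optional[str],
    parameter: str,
    bracket: tuple[float, float],
    tol: float,
    out_dir,
    payer: str = "medicare",
) -> Path:
    out = _prep(out_dir)
    params = resolve_parameters(config, payer)
    record: dict = {"parameter": parameter, "bracket": list(bracket), "tolerance": tol, "payer": payer}
    try:
        res = find_threshold(params, parameter, bracket, tol)
        record.update(
            threshold=res.threshold,
            achieved_bracket=list(res.bracket),
            achieved_tolerance=res.tolerance,
            predicate=res.predicate,
            no_crossing=False,
        )
    except NoCrossingError as exc:
        record.update(threshold=None, no_crossing=True, detail=str(exc))
    path = out / f"threshold_{parameter.replace('.', '_')}_{payer}.json"
    path.write_text(json.dumps(record, indent=2))
    manifest = RunManifest(command=f"threshold {parameter}", config=config, seed=None, outputs=[str(path)])
    manifest.write(out)
    return path


def run_psa_report(
    config: Optional[str],
    out_dir,
    n_max: int = 2000,
    seed: int = 0,
    wtp: float = 50_000.0,
    payer: str = "medicare",
    convergence_tol: float = 0.001,
) -> Path:
    out = _prep(out_dir)
    params = resolve_parameters(config, payer)
    result = run_psa(params, n_max=n_max, convergence_tol=convergence_tol, seed=seed, wtp=wtp, payer=payer)
    samples_path = out / "psa_samples.csv"
    result.to_frame().to_csv(samples_path, index=False)
    summary = summarize_ce_plane(result, wtp)
    summary_path = out / "psa_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "n_draws": result.n_draws,
                "wtp": wtp,
                "converged_at": result.converged_at,
                "convergence_tol": convergence_tol,
                "inb_mean": summary.inb_mean,
                "inb_ci95": list(summary.inb_ci95),
                "prob_positive_inb": summary.prob_positive_inb,
                "quadrant_fractions": summary.quadrant_fractions,
                "n_excluded_icer": result.n_excluded_icer,
            },
            indent=2,
        )
    )
    manifest = RunManifest(
        command=f"psa n={n_max}", config=config, seed=seed,
        outputs=[str(samples_path), str(summary_path)],
    )
    manifest.write(out)
    return summary_path


def run_propensity_report(out_dir, n: int = 5000, seed: int = 0) -> Path:
    """Synthetic-study workflow: outcome model, propensity scores, matching."""
    out = _prep(out_dir)
    spec = SyntheticStudySpec(n=n, seed=seed)
    records = generate_study(spec)

    outcome_model = fit_logistic(records, OUTCOME_COVARIATES, outcome="success")
    wald_path = out / "outcome_model_wald.csv"
    outcome_model.wald_table().to_csv(wald_path, index=False)

    treatment_model = fit_logistic(records, TREATMENT_COVARIATES, outcome="device_used")
    scores = score(treatment_model, records)
    treated = [r for r, s in zip(records, scores) if r.device_used == 1]
    control = [r for r, s in zip(records, scores) if r.device_used == 0]
    st = scores[[r.device_used == 1 for r in records]]
    sc = scores[[r.device_used == 0 for r in records]]
    matched = match(st, sc)
    pairs_path = out / "matched_pairs.csv"
    pd.DataFrame(matched.pairs, columns=["treated_index", "control_index"]).to_csv(
        pairs_path, index=False
    )
    balance = balance_check(treated, control, matched)
    balance_path = out / "balance.csv"
    balance.to_csv(balance_path, index=False)

    manifest = RunManifest(
        command=f"propensity n={n}", config=None, seed=seed,
        outputs=[str(wald_path), str(pairs_path), str(balance_path)],
    )
    manifest.write(out)
    return balance_path


def run_simulate(
    config: Optional[str],
    out_dir,
    arm: str = SOC,
    payer: str = "medicare",
    n: int = 10_000,
    seed: int = 0,
) -> Path:
    """Microsimulation run: state frequencies and per-patient summaries."""
    out = _prep(out_dir)
    params = resolve_parameters(config, payer)
    strategy = make_strategy(arm, payer, params)
    trajectories = simulate_patients(params, strategy, n, seed=seed)
    freq = occupancy_frequencies(trajectories)
    freq_path = out / f"microsim_frequencies_{arm}_{payer}.csv"
    df = pd.DataFrame(freq, columns=[s.name.lower() for s in HealthState])
    df.insert(0, "stage", np.arange(freq.shape[0]))
    df.to_csv(freq_path, index=False)
    summary_path = out / f"microsim_summary_{arm}_{payer}.json"
    costs = np.array([t.cost_accrued for t in trajectories])
    qalys = np.array([t.qaly_accrued for t in trajectories])
    summary_path.write_text(
        json.dumps(
            {
                "n": n,
                "arm": arm,
                "payer": payer,
                "mean_cost": float(costs.mean()),
                "se_cost": float(costs.std(ddof=1) / np.sqrt(n)),
                "mean_qaly": float(qalys.mean()),
                "se_qaly": float(qalys.std(ddof=1) / np.sqrt(n)),
                "mean_colonoscopies": float(np.mean([t.n_colonoscopies for t in trajectories])),
            },
            indent=2,
        )
    )
    manifest = RunManifest(
        command=f"simulate {arm} {payer} n={n}", config=config, seed=seed,
        outputs=[str(freq_path), str(summary_path)],
    )
    manifest.write(out)
    return summary_path
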