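"""Probabilistic sensitivity analysis at the shipped distributions.

2,000 Monte-Carlo draws with common random parameters across arms; monitors
the 0.1% running-mean-ICER convergence rule and summarises the
cost-effectiveness plane and incremental net benefit at $50,000/QALY.
"""

import json
from pathlib import Path

from colocea.report import run_psa_report

OUT = Path(__file__).resolve().parents[1] / "results" / "psa"

summary_path = run_psa_report(config=None, out_dir=OUT, n_max=2000, seed=1, wtp=50_000.0)
summary = json.loads(Path(summary_path).read_text())

print(f"draws: {summary['n_draws']}  (seed 1)")
print(f"running-mean ICER satisfied the 0.1% rule from draw: {summary['converged_at']}")
print(f"incremental net benefit at $50k/QALY: mean ${summary['inb_mean']:.0f}, "
      f"95% interval (${summary['inb_ci95'][0]:.0f}, ${summary['inb_ci95'][1]:.0f})")
print(f"P(INB > 0) = {summary['prob_positive_inb']:.3f}")
print("cost-effectiveness plane quadrants:", summary["quadrant_fractions"])
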