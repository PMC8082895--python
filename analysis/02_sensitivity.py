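"""One-way sensitivity analyses and threshold searches.

Sweeps screening compliance 20-80% at private-pay rates (the published
compliance grid) and the device list price, then bisects for the two
decision thresholds at Medicare rates: the compliance level at which
standard of care becomes cheaper, and the device price with the same
property.  The compliance search is expected to report *no crossing*: in
this model the cleansing strategy stays cheaper at every compliance level
(see docs/methods.md on reproduction limits).
"""

import json
from pathlib import Path

import pandas as pd

from colocea.report import run_sweep, run_threshold

OUT = Path(__file__).resolve().parents[1] / "results" / "sensitivity"

sweep_path = run_sweep(
    config=None,
    parameter="p_compliance_screening",
    grid=[0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80],
    out_dir=OUT,
    payer="private",
)
sweep = pd.read_csv(sweep_path)
print("compliance sweep (private pay):")
print(sweep.to_string(index=False))

price_sweep = run_sweep(
    config=None,
    parameter="cost_purevu_device",
    grid=[0, 500, 750, 1000, 1500, 1753, 2000, 3000],
    out_dir=OUT,
    payer="medicare",
)
print(f"\ndevice-price sweep written to {price_sweep}")

for parameter, bracket, tol in [
    ("cost_purevu_device", (0.0, 5000.0), 1.0),
    ("p_compliance_screening", (0.05, 0.95), 0.005),
]:
    path = run_threshold(config=None, parameter=parameter, bracket=bracket, tol=tol,
                         out_dir=OUT, payer="medicare")
    record = json.loads(Path(path).read_text())
    if record.get("no_crossing"):
        print(f"{parameter}: no crossing in {bracket} "
              "(the cleansing strategy is cheaper across the whole range)")
    else:
        print(f"{parameter}: threshold = {record['threshold']:.4g}")
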