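# colocea

Lifetime Markov cost-effectiveness model of intra-procedural colon
cleansing (the PureVu oversleeve) versus standard-of-care colonoscopy for
average-risk colorectal-cancer screening in the United States.

About 25% of screening colonoscopies are performed on inadequately prepped
colons, where polyp miss rates reach 42–48% and guidelines call for a
repeat exam that roughly 40–45% of patients never receive.  An
intra-procedural cleansing device converts most of these exams into
adequate ones at a $750 list price.  This package asks the
health-economics question: over the remaining lifetime of a 60-year-old
screening cohort, does avoiding rescheduled exams and missed adenomas pay
for the device?

It is written for health-economics and outcomes-research analysts: a
library (`colocea`) holding every computation, numbered analysis scripts
(`analysis/`) reproducing the study tables, and a CLI (`colocea`) for
ad-hoc runs.

## Model in brief

A nine-state annual-cycle Markov cohort model (screening-compliant, lapsed,
never-screens, adenoma surveillance, early CRC, advanced CRC, remission,
CRC death, other death) over a 40-year horizon, with the colonoscopy
decision tree embedded at 10-yearly screening stages.  Strategies are
compared by discounted (3%/year) lifetime cost and QALYs:

- average ratio per arm:  cost/QALY;
- incremental cost-effectiveness ratio:  ICER = ΔC/ΔE;
- incremental net benefit:  INB(λ) = λ·ΔE − ΔC  at willingness-to-pay λ.

A strategy *dominates* when it is both cheaper (ΔC < 0) and more effective
(ΔE > 0).  One-way sweeps and bisection threshold searches probe
compliance and device price; a Monte-Carlo probabilistic sensitivity
analysis (PSA) propagates parameter uncertainty with a 0.1%
running-mean-ICER convergence rule; an individual-level microsimulation
serves as an internal oracle for the cohort engine; and a
propensity-scoring module (IRLS logistic regression, greedy caliper
matching) mirrors how observational colonoscopy studies are balanced
before feeding such a model.  Full model documentation, including the
calibration of supplementary-sourced defaults and the limits of the
reproduction, is in [docs/methods.md](docs/methods.md).

## Worked example

```python
from colocea import default_paper_parameters, make_strategy, run_arm, compare

params = default_paper_parameters("medicare")
soc = run_arm(params, make_strategy("soc", "medicare", params))
purevu = run_arm(params, make_strategy("purevu", "medicare", params))
print(f"SOC     ${soc.total_cost:.0f}  {soc.total_qaly:.2f} QALYs")
print(f"PureVu  ${purevu.total_cost:.0f}  {purevu.total_qaly:.2f} QALYs")
inc = compare(purevu, soc)
print(f"delta   ${inc.delta_cost:+.0f}, {inc.delta_qaly:+.3f} QALYs -> {inc.dominance}")
```

prints

```
SOC     $6602  15.10 QALYs
PureVu  $6341  15.11 QALYs
delta   $-261, +0.006 QALYs -> intervention_dominates
```

i.e. under the shipped Medicare base case the cleansing strategy saves
$261 per patient over the cohort's lifetime while slightly increasing
QALYs, so it dominates: no willingness-to-pay threshold is needed to
prefer it.  At private-payer reimbursement the saving grows to $430.  The
analysis scripts add the sensitivity layers, e.g.

```sh
python analysis/01_base_case.py      # lifetime table + national projections
python analysis/02_sensitivity.py    # compliance/price sweeps + thresholds
python analysis/03_psa.py            # 2,000-draw PSA with convergence check
python analysis/04_propensity.py     # synthetic-study propensity workflow
python analysis/05_microsim_validation.py
```

`02_sensitivity.py` reports that standard of care becomes the cheaper
option only when the device price exceeds ~$1,749, and that no screening
compliance level in (5%, 95%) reverses the cost ordering.  `03_psa.py`
reports the running-mean ICER satisfying the 0.1% rule after ~1,400 draws
with a positive incremental net benefit in >99% of draws.

## Layout

```
src/colocea/      config, strategies, engine, cea, sensitivity, psa,
                  propensity, synth, report, cli
configs/          base_case.yaml — the shipped parameter set
analysis/         numbered narrative drivers writing results/
tests/            unit + property tests, acceptance checks
docs/methods.md   model documentation and calibration notes
```
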