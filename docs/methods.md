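# Methods

`colocea` implements a lifetime Markov cohort model comparing two
colonoscopy strategies for average-risk colorectal-cancer (CRC) screening in
the United States: standard of care (SOC), in which an inadequately prepped
colon degrades the exam and triggers a rescheduled repeat, and an
intra-procedural cleansing strategy (the PureVu oversleeve device), which
irrigates and evacuates the colon during the index procedure.  The package
re-implements a published TreeAge-based cost-effectiveness analysis of this
comparison; the sections below document the model, the choices made where
the published description is incomplete, and the limits of the
reproduction.

## Model structure

**States.** Nine health states: `COMPLIANT_SCREENING` (in the screening
programme), `NONCOMPLIANT_POST_COLONOSCOPY` (had at least one exam, then
lapsed), `NONCOMPLIANT_WITH_SYSTEM` (never screens), `ADENOMA_SURVEILLANCE`
(post-polypectomy surveillance), `EARLY_CRC`, `ADVANCED_CRC`, `REMISSION`,
and two absorbing death states (`DEATH_CRC`, `DEATH_OTHER`).  The chain is
time-inhomogeneous: a fresh annual transition matrix embeds the colonoscopy
decision tree at screening stages and only natural history elsewhere.

**Cohort and time.** The cohort is an "average" 60-year-old (54% male), split
at entry into compliant (60%) and never-compliant (40%) — noncompliance with
the system is modelled as a permanent trait, not a per-round coin flip.
Cycles are annual, the horizon is 40 years (age 100), and both costs and
QALYs are discounted at 3%/year with the end-of-cycle convention
(stage *t* accruals carry weight (1.03)^-t, computed on start-of-cycle
occupancy).  A half-cycle correction is available as a switch and off by
default.

**Mortality.** Other-cause mortality is a flat annual hazard of 0.028629,
calibrated so mean truncated residual life over the 40-year horizon equals
the 24 years expected for this cohort.  A naive exponential hazard of 1/24
over a 24-year horizon cannot reproduce the published discounted QALY scale
(it caps discounted life-years at ~12, versus the ~15.1 QALYs reported), so
the flat-hazard/long-horizon calibration is used instead.  Cancer states
carry excess annual death probabilities of 1/23 − 1/24 (early, treated) and
1/4.8 − 1/24 (advanced), reproducing the 23- and 4.8-year life expectancies.

**The colonoscopy episode.** Per attended exam: 25% of colons present
inadequately prepped.  Under SOC the exam proceeds with reduced adenoma
sensitivity (0.55 versus 0.85 with adequate prep, i.e. a 45% miss rate in
the published 42–48% band) and the patient returns for a repeat exam with
probability 0.575 (midpoint of the published 55–60% within 3 years),
modelled as an episode-level branch resolved within the screening year.
Under the cleansing strategy the device is deployed in the
inadequately-prepped 25% of exams at a $750 list price and restores adequate
prep in 95% of them; residual failures follow the SOC repeat pathway.  An
inadequately prepped exam that is never repeated ends the individual's
participation in screening (a guideline failure → lapsed state) unless the
adenoma was found despite the poor prep.  Detected adenomas are removed
(polypectomy cost) and the patient enters annual colonoscopic surveillance,
which is abandoned with probability 0.8 per skipped year.

**Compliance as one construct.** The 60% compliance figure drives the entry
split, re-attendance at 10-yearly repeat screens, and (by default)
surveillance attendance; the repeat-after-inadequate-prep probability scales
proportionally with compliance relative to the 60% base.  This treats
"compliance to colonoscopy" as a single behavioural trait, matching how the
published analysis varies a single compliance rate.

**Natural history.** Annual CRC onset for an unprotected adult is adenoma
prevalence (0.20) x annual progression probability (0.0089, calibrated).
Engagement with screening reduces onset by a relative risk of 0.05 (compliant
or under surveillance), consistent with published 76–90% risk reductions for
properly executed screening; the reduced-form rate on the compliant state
absorbs the detection-and-removal mechanism that a nine-state aggregate
chain cannot track per individual.  Onsets present advanced-stage with
probability 0.25 if unscreened/lapsed versus 0.05 inside the programme —
the stage-shift that makes missed screening expensive.  Treated early
cancer progresses to advanced disease at 0.02/year and reaches remission at
0.15/year; remission relapses at 0.01/year.

**Costs (2019 USD).** Colonoscopy facility $970 plus $220 professional fee,
polypectomy increment $250, complication $8,000 at 0.3%/exam, early-CRC care
$12,000/year, advanced-CRC care $150,000/year, remission surveillance
$1,500/year.  Private-payer reimbursement multiplies fee-schedule components
by 2.055 (midpoint of the published 1.63–2.48 range); the device is billed
at list price, and only a 15% fee-schedule share of cancer care scales with
the payer (the published private/Medicare cost ratio of ~1.33 is itself
incompatible with the full multiplier applying to all costs, so most cancer
care — drug acquisition in particular — is treated as payer-invariant).

**Utilities.** 0.95585/year without cancer (also in surveillance), 0.74 with
treated early cancer, 0.55 with advanced cancer, 0.83 in remission, 0 when
dead.  The no-cancer utility is calibrated jointly with the horizon/hazard
choice to the published 15.10 discounted QALYs for the SOC arm.

## Calibration and reproduction limits

The published report prints only headline inputs (compliance 60%, prep rates
25%/5%, device $750, discount 3%, life expectancies 24/23/4.8 years, payer
multiplier range); the full variable, distribution and cost-equation tables
live in supplementary files that are not reproduced in the main text.  All
such values ship as *supplementary-sourced* defaults: structure and cost
levels were fixed once at literature-plausible values, and three level
parameters — the adenoma progression probability, the surveillance-lapse
probability and the no-cancer utility — were calibrated by least squares
against the published base-case outputs.

The reproduction is deliberately honest about where it lands.  Three
arithmetic identities constrain any model of this nine-state structure:

1. the private-minus-Medicare spread pins discounted fee-schedule spending
   per SOC patient at about $2,200;
2. the Medicare cost level then fixes the cancer-care budget at about
   $4,700, roughly three quarters of which is generated by the 40%
   never-screened fraction *identically in both arms*, capping the
   achievable between-arm cancer-cost difference near $450;
3. the published $1,753 device-price threshold forces lifetime device
   spending to equal about three quarters of the per-patient saving.

Jointly these cap the per-patient Medicare saving near $260–460 versus the
published $833, and no compliance level in (0, 1) makes SOC cheaper (the
published 28% threshold is also in tension with the published private-pay
compliance grid, where the cleansing strategy is still cheaper at 20%
compliance).  The shipped configuration is the constrained optimum: QALYs
match to <1%, the device-price threshold reproduces within $5, cost cells
sit 3–5% from the printed values, savings are $261 (Medicare) and $430
(private), and the compliance search correctly reports that no crossing
exists.  The acceptance tests assert the published values at their stated
tolerances and are expected to fail exactly where this analysis says they
must; they are not loosened.

## Probabilistic sensitivity analysis

Each distributed parameter carries an independent sampling distribution:
betas centred on base values for probabilities and utilities (effective
sample sizes 150–2,000), gammas with 15% coefficient of variation for
costs, and a uniform over 1.63–2.48 for the private multiplier.  Both arms
are evaluated on the same draw (common random parameters).  The running
mean ICER is monitored with the 0.1% relative rule over a trailing window
of 100 draws; with the shipped distributions the rule is met after roughly
1,200–1,600 draws (same order as the published 1,728 iterations).  Draws
with |ΔQALY| < 1e-9 are excluded from the ICER mean (the count is
reported); the incremental net benefit, defined for every draw, is the
primary summary.  One seed generates per-draw substreams deterministically,
so exports are byte-for-byte reproducible.

## Synthetic data

The microsimulation draws individual patients through the same transition
structure, resolving each colonoscopy episode event by event (attendance,
prep adequacy, device deployment, repeat exam, detection, polypectomy,
complication), which cross-checks both the cohort occupancy (exact
expectation of the state frequencies) and the closed-form episode-cost
expectation through an independent code path.  The study generator draws
age, sex, device use and cecal-intubation depth and produces a logistic
success outcome with configurable coefficients for the propensity module.
Neither generator attempts to emulate real patient-level registries:
covariates are independent by construction, trajectories inherit every
simplification of the cohort model (no secular trends in costs or
epidemiology, no age-specific life tables, no correlation between
behaviour and risk), so passing tests demonstrate internal consistency of
the implementation, not external validity of the model.

## Propensity module

The logistic fit is iteratively reweighted least squares with a 1e-8
log-likelihood tolerance, raising distinct errors for constant outcomes and
for separation (coefficient norm guard plus singular-information detection).
Two models are exposed: the outcome model (successful colonoscopy ~ age +
sex + device + cecal intubation), reported as a Wald table, and the
treatment model (device ~ age + sex) whose fitted probabilities are matched
greedily 1:1 on the logit scale, treated units in descending score order,
controls without replacement, default caliper 0.2 SD of the pooled logit
scores.  Greedy matching is deterministic and within-caliper by
construction; tests compare it against the optimal-assignment solution on
small instances.

## Numerical choices

Transition rows are checked to sum to one within 1e-12 (with an explicit
error when branch probabilities compose to a negative residual); occupancy
conservation is asserted at 1e-9 per stage.  Bisection for thresholds is
pure interval halving — deterministic, tolerance 0.5 percentage points for
probabilities and $1 for prices — and a same-sign bracket raises a
no-crossing error rather than returning a value.  Logistic linear
predictors are clipped at ±30 before the inverse link; propensity scores
are clipped away from {0, 1} before the logit transform.  Reported tables
round dollars to integers and QALYs to two decimals; full precision is kept
internally and rounding never feeds back into computation.

## Known limitations

- The nine-state aggregate chain cannot track adenoma carriage per
  individual; screening protection is therefore a reduced-form relative
  risk rather than an explicit detect-and-remove mechanism.
- Other-cause mortality is flat in age; no sex-specific life tables (sex
  enters as a cohort mix and as a covariate of the synthetic studies).
- Parameter draws in the PSA are independent; no correlation structure.
- Indirect costs (patient time, travel) are out of scope, as is inflation
  adjustment of historical reimbursements: the configuration is assumed to
  be stated in 2019 USD.
- The published headline results are mutually inconsistent under this
  structure (see "Calibration and reproduction limits"); users calibrating
  to different targets should start from `configs/base_case.yaml` and the
  calibration discussion above.
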