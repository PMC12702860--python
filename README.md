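# preterm-bia

A budget-impact model of patterned, frequency-modulated oro-somatosensory
stimulation (PFOS) versus standard-of-care oral stimulation (SoC) for
developing non-nutritive sucking (NNS) in preterm infants (gestational age at
birth, GAB, 25–30 weeks).  Non-nutritive sucking is a prerequisite for full
oral feeding (FOF), which in turn gates NICU discharge — so an intervention
that shortens time-to-FOF mainly pays for itself through saved level-III NICU
days.

The package is written for health-economics and outcomes-research analysts:
it is a library first (importable API plus `examples/`), with a thin
`preterm-bia` command line on top.

## Model

A decision tree pre-stratifies a cohort of *N* = 100 hypothetical infants by
predicted FOF achievement:

* NNS already developed at birth → **Markov 1**, achieved-FOF state;
* training succeeds → **Markov 1**, NICU training state;
* training fails → **Markov 2** (discharged home with a naso-/orogastric tube,
  NGT).

The two Markov models are structurally identical: pre-training NICU → NICU
training & follow-up → (lower-acuity ward) → home, where each of five yearly
home clusters carries year-specific risks of home-managed infection,
rehospitalization and death; death is absorbing and reachable from every
living state.  The grid uses daily cycles to day 180 and half-monthly cycles
to year 5, with per-cycle probabilities from constant-hazard compounding,
`p_cycle = 1 − (1 − p_source)^(L/T)`.  Markov 2's NICU discharge probability
is scaled by the time-to-discharge factor TTD (base 0.8; TTD = 1 makes the
two models identical).

Costing perspectives:

* **payer** — 5 years, daily hospital *charges* plus per-event home costs;
  also translated to cost per member per month,
  `PMPM = total / (covered lives × 60)`, with covered lives back-calculated
  from the share of women of reproductive age, the fertility rate, and the
  share of births at GAB 25–30;
* **hospital** — 1 year, charges converted via a cost-to-charge ratio, home
  events excluded, hands-on staff time for NNS training included, reported by
  FOF / non-FOF group.

Uncertainty: a Monte Carlo PSA (gamma for costs/charges, lognormal for odds
ratios, normal for mid-range proportions, beta near the extremes; 10%
relative sd in general, 20% for costs), a ±20% one-way tornado analysis, a
TTD sweep (0.5–1.2), a device-cost threshold analysis on the shared PSA
draws, and a GAB 25–28 / 29–30 subgroup analysis.

The original input tables are not distributed with this package; a calibrated
synthetic fixture stands in for them (see `docs/methods.md`).  Its base-case
run reproduces the headline anchors: per-arm mean NICU stays of 65.8 / 59.8
days, 982,791 covered lives, a ~92% NICU share of payer costs, and PMPM of
$0.37 (PFOS) vs. $0.41 (SoC).

## Worked example

```python
from preterm_bia import (Arm, Perspective, attach_costs, base_case,
                         covered_lives, default_fixture, pmpm, run_cohort)

ps = default_fixture()
traces = {arm: run_cohort(ps, arm) for arm in Arm}
payer = {arm: attach_costs(traces[arm], ps, Perspective.payer) for arm in Arm}
print(round(payer[Arm.PFOS].total), round(payer[Arm.SOC].total))
lives = covered_lives(ps).lives
print(round(pmpm(payer[Arm.SOC].total, lives, 60), 2))
```

prints

```
22000546 24006764
0.41
```

— the intervention arm costs $22.0M versus $24.0M for standard care over five
years for 100 infants (a $2.0M saving, −600 NICU days), and the SoC arm works
out to $0.41 per insured member per month across 982,791 covered lives
($0.37 for PFOS).  `python examples/base_case.py` prints the full per-category
table; the other `examples/` scripts run the PSA, tornado, TTD/threshold and
subgroup analyses.

The same analyses are available from a shell:

```bash
preterm-bia base --perspective payer --out results/
preterm-bia psa --n 5000 --seed 1 --out results/
preterm-bia owsa --perspective hospital --plot --out results/
```

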