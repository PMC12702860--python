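# Methods

This note documents the model implemented in `preterm_bia`: its structure and
assumptions, the synthetic parameter fixture and what it does and does not
emulate, the numerical conventions, and the design decisions taken where the
published description left the structure open.

## Care-pathway model

**Population.** 100 hypothetical preterm infants, gestational age at birth
(GAB) 25–30 weeks, entering a level-III NICU at birth.  The cohort is an
expected-value (Markov cohort) model: occupancy is real-valued mass, not
individuals.

**Decision tree.** Three branches fix each infant's Markov membership at
entry: NNS developed at birth (enters Markov 1 in the achieved-FOF /
training-follow-up state), successful NNS training (Markov 1, pre-training
NICU state), unsuccessful training (Markov 2, pre-training NICU state).
Branch probabilities are arm-specific; masses sum exactly to the cohort size.

**States.** Each Markov model has: pre-training NICU, NICU training &
follow-up, lower-acuity ward, and — replicated in five one-year clusters —
home-healthy, home-managed infection (a one-cycle transient), and
rehospitalized; plus absorbing death.  Hospital states are unreachable from
home except through rehospitalization.  Markov 2 infants leave the NICU with
a naso-/orogastric tube: they incur a per-discharge NGT cost and carry
elevated first-year home-infection odds (an odds-ratio parameter) and an
elevated first-year rehospitalization risk (a multiplicative factor).

**Time grid.** Daily cycles to day 180, 15-day cycles to day 1825 (the final
cycle is truncated at the horizon).  In-hospital dynamics need daily
resolution; post-discharge risks are slow enough for half-monthly cycles.
The daily phase is anchored to model time (days since birth), not NICU entry.
At each 365-day boundary, home-cluster occupancy migrates to the next year's
cluster, which carries that year's infection, rehospitalization and mortality
inputs.  Because 365 is not a multiple of 15, a year boundary can fall inside
a cycle; clusters are assigned by cycle start day.

**Transitions.** All inputs are stated per their natural period (per day or
per year) and rescaled to the cycle by constant-hazard compounding.  Within a
cycle, death takes precedence, then discharge, then events; the residual mass
remains in state, so rows are exactly stochastic (checked to 1e-12).  The
non-FOF group's NICU discharge probability is the FOF group's scaled by the
TTD factor, `min(ttd × p, 1)` — the simplest monotone rule with the required
identity at ttd = 1 (base case 0.8).  Training start is a deterministic
transfer at a configurable day (default 21), executed at cycle start.

**Event accounting.** NICU and ward patient-days are tallied at daily
resolution inside each cycle: an occupant with per-day exit probability *d*
contributes `(1 − (1−d)^L)/d` expected days to a cycle of length *L*.  This
is exact for the discrete daily process (it is not a half-cycle correction;
transitions still resolve at cycle end) and makes a constant daily discharge
probability *p* yield a mean stay of exactly 1/*p* on the mixed grid, which
the calibration relies on.  In-hospital infections are costed tallies that do
not alter transitions or length of stay — any such effect is absorbed into
the calibrated discharge hazards.  Rehospitalization is costed per admission;
its stay occupies the rehospitalized state for a configurable mean length
(default 9 days).  Mortality is a background hazard per setting: a daily
in-hospital probability and year-specific annual at-home probabilities.

## Costing

* **Payer** (5-year horizon): per-day charges for NICU (level III) and
  lower-acuity ward (level I — the general ward is priced identically), and
  per-event costs for in-hospital infections, NGT discharges, home
  infections and rehospitalizations.
* **Hospital** (1-year horizon): charges converted through a single scalar
  cost-to-charge ratio, home-event costs excluded, per-group (FOF vs.
  non-FOF) reporting split into pre-training NICU, training & follow-up
  (NICU training days + ward + in-hospital infections), and hands-on staff
  time (`patients × sessions × minutes × wage / 60`; the non-FOF group's
  sessions are scaled up by a factor).  The 365-day truncation caps
  person-days exactly inside the boundary cycle via the stored daily exit
  probabilities; event tallies in that cycle are prorated linearly (relative
  error ~1e-7 of the hospital total).
* **PMPM**: covered lives = `round(n / (prop_women × fertility ×
  prop_preterm))`; member-months use 60 months (5 × 12) for the payer
  horizon.  All accumulation is full-precision; totals are `math.fsum` of the
  category values actually rendered, so rendered tables re-sum bit-exactly.
  Rounding (cents for PMPM, dollars for display) happens only at rendering.
* No discounting (standard for budget-impact horizons) and no
  reimbursement/revenue modelling.

## Uncertainty

* **PSA**: each parameter gets a distribution by kind — gamma for
  costs/charges, lognormal for odds ratios, normal for probabilities in
  [0.10, 0.90] and other continuous inputs, beta for proportions outside
  that band; zero-uncertainty parameters are degenerate.  All families are
  moment-matched: sampled mean = base value, sd = value × fraction (10%
  default, 20% for costs).  The lognormal is mean-matched, not
  median-matched, to keep this moment contract.  Draws outside a parameter's
  bounds are resampled (up to 1,000 rounds, then clamped).  One joint draw
  per iteration feeds both arms, so shared inputs are correlated across arms
  while arm-specific efficacy inputs (separate named parameters) vary
  independently; draws are mutually independent across parameters.  The 95%
  uncertainty interval is the empirical 2.5/97.5 percentile (linear
  interpolation) of per-iteration differences; the probability of cost
  saving is the share of iterations with SoC total > PFOS total.  Identical
  master seeds reproduce identical iteration vectors.
* **OWSA**: every scalar parameter except the cohort size is set to 80% and
  120% of base (clamped to bounds, flagged when clamped); the top 10 by
  absolute spread form the tornado.
* **TTD sweep**: deterministic reruns at ttd ∈ {0.5, …, 1.2}.
* **Threshold analysis**: a per-patient device cost is applied post hoc to
  the stored PSA savings (`P(saving > c × n)`), so the curve is
  nonincreasing and equals the PSA probability at c = 0.
* **Subgroups**: GAB 25–28 and 29–30 run as independent 50-infant cohorts
  with group-specific rehospitalization risks and length-of-stay inputs;
  pooled results are exact sums.

## The synthetic fixture

The original supplementary input tables are not available to this package,
so `synthetic.py` ships a calibrated stand-in.  Every entry is labelled in
its `note` field as published-anchored, back-solved, or placeholder.  The
calibration passes, run by `build_default_fixture()` and frozen into the
packaged YAML (regenerable with `preterm-bia make-fixture`):

1. the covered-lives denominator is back-solved so lives round to exactly
   982,791;
2. the per-arm training-state means (`time_to_fof_*`) are root-found
   (Brent's method against full engine runs) so the base-case arm mean NICU
   stay is 65.8 days (SoC) and 59.8 days (PFOS) — the published per-arm
   length-of-stay inputs;
3. the NICU daily charge is back-solved so the SoC payer NICU category
   matches the published $22.18M magnitude (≈ $3,371/day, within the
   plausible level-III range).

Remaining values are placeholders chosen once at realistic magnitudes
(e.g. ward $985/day, rehospitalization $13,900/episode, cost-to-charge ratio
0.44, ~123 rehospitalizations and ~42 home infections per 100 infants over
five years, ~6 NGT discharges per 100).  A mean-stay calibration utility
(`calibrate_discharge_prob`) inverts the engine's geometric stay: closed form
1/target without mortality, bracketed root-finding with a competing daily
death hazard.

**What the fixture does not emulate.**  The published clinical table's NICU
day counts (≈54/49 days per infant) are not mutually consistent with the
published per-arm length-of-stay inputs (65.8/59.8 days); this fixture
follows the length-of-stay inputs, so its NICU-day difference is ≈600 per
100 infants rather than the printed 577, and its per-category splits match
the published magnitudes rather than the exact figures.  The small (<2%)
published *decreases* in home infections and rehospitalizations under PFOS
are not reproduced in sign: with earlier discharge and slightly more NGT
carriers, the reconstructed state graph gives slight increases instead; no
mechanism in the described structure yields the published sign while
preserving the length-of-stay calibration.  Passing tests therefore show
that the machinery is correct and calibrated to the headline anchors, not
that the fixture equals the original inputs.

## Numerical choices and scaled-down analyses

Mass conservation is enforced every cycle at 1e-9; matrix rows at 1e-12.
The test suite exercises a 100,000-individual event-driven microsimulation
(agreement within 3 Monte Carlo SEs), matrix-power equivalence on
time-homogeneous segments (1e-10), and a 500-iteration PSA (the default
analysis uses 5,000 iterations; 500 keeps the suite quick while leaving
percentile estimates stable to a few points).  Hypothesis-based property
tests run derandomized.  Degenerate inputs (zero cohort, zero uncertainty,
empty grids, certain events rescaled to shorter cycles) raise or collapse
explicitly rather than silently.

## Known limitations

* No individual-level covariates, no parental quality-of-life or
  neurodevelopmental outcomes, no currency conversion beyond USD.
* A single scalar cost-to-charge ratio is applied uniformly.
* The NGT-discharge cost is per event (a per-day-at-home variant is not
  implemented).
* Whether the 10%/20% uncertainty levels are relative standard deviations or
  interval half-widths is ambiguous in the source description; they are
  implemented as relative standard deviations.
* The lower-acuity ward is an optional post-NICU stop with a branch
  probability; whether it substitutes part of the NICU stay is not
  resolvable from the published structure.
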