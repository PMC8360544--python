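# Methods

## Model structure and assumptions

The model is a single-pass decision tree over a 30-day horizon — no
Markov cycles, discounting or half-cycle correction, appropriate for a
short acute episode. Both arms share one topology: pneumonia {yes, no}
→ location {critical care, general ward} → (critical care only)
mechanical ventilation {yes, no} → outcome {died, discharged by day
30}. That yields 12 terminal pathways per arm (six per pneumonia
status). Child probabilities at every node sum to one by construction,
and the enumeration asserts conservation to 1e-12.

Assumptions carried by the implementation:

- **Arm derivation.** The intervention (mouthwash) arm is the control
  arm with `p × (1 − RRR)` applied to pneumonia incidence and, among
  pneumonia patients, critical-care admission, ventilation and both
  critical-care death probabilities. General-ward death among pneumonia
  patients and *all* no-pneumonia parameters are identical across arms.
  The source tables annotate some no-pneumonia intervention rows as
  RRR-reduced while the stated assumptions say identical; the identical
  reading is implemented — it is the only one consistent with the
  published incremental cost (a 30% cut to no-pneumonia critical-care
  admission would roughly triple the saving).
- **Ward transfers.** Transfers between ward and critical care are not
  costed as separate states: time transferred is assumed symmetric
  between directions, so the costs cancel and the six leaf
  length-of-stay classes suffice.
- **Decedent stays.** Stay lengths are not published by outcome, so
  decedents accrue the full class mean stay. This is the presumed main
  source of the ≈1% gap between this implementation's expected costs
  ($3,993 / $3,705) and the published $3,958 / $3,675, and is the
  reason the cost checks carry a ±$40 (arms) / ±$15 (difference)
  tolerance.
- **Costing conventions.** Ventilation ($89) is per episode, once per
  ventilated patient; the pneumonia episode cost ($3,752) is added once
  per pneumonia patient on top of bed-day/ICU-day costs; the procedure
  cost ($1,423) applies to every patient in both arms and cancels in
  differences but is kept for absolute reporting.
- **Effect coding.** Effect is 1 for no-pneumonia pathways, 0 for
  pneumonia pathways; the effect axis everywhere is the *reduction in
  the proportion of pneumonia patients*, not QALYs, and willingness to
  pay is priced per unit of that proportion.

## Parameters

- Probabilities are stored at full `events/total` precision where counts
  exist (e.g. pneumonia 39/931 = 0.041890); printed 2-dp values are used
  only as a ±0.005 cross-check. One control row ("died, critical care,
  no ventilation", 17/42) has a denominator inconsistent with the 21
  critical-care admissions upstream; it is used as printed. Because
  death probabilities do not affect costs (decedents accrue full class
  stays), this only widens one cost-neutral beta distribution.
- RRR default 0.3 (a deliberately conservative discount of the 0.52
  effect reported in cardiac surgery); the deterministic analyses sweep
  it down to 0.01.
- The control-arm ventilation probability among pneumonia patients
  (0.25) is a beta parameter published without counts; it receives a
  configurable effective sample size (default 39, the pneumonia cohort
  size). Expert-opinion values marked fixed (no-pneumonia ventilation
  0.24 and its death probability 0.04) are point masses everywhere.
- Pandemic overlay (scenario 2): the control pneumonia probability is
  raised *before* the RRR derivation and every patient accrues $254.
  Two increments are implemented because the source is internally
  inconsistent: the stated +1.8 percentage points (`absolute_pp`,
  default) and +0.0028 (`calibrated`), the value implied by the
  published scenario-2 proportions (0.045 / 0.031). Neither is guessed
  to be "intended"; every report echoes the mode used. Overlay and
  derivation commute in the algebraic sense checked by a property test;
  an overlay that would push a probability past 1 raises instead of
  clamping.

## Currency transfer

Costs enter the model as published 2020 international-dollar values; the
currency module is a supporting, auditable utility, because the
published adjusted column is not reproducible row-by-row from the
printed factors (different rows imply different conversion routes). It
implements: market-basket index (source basket total / target basket
total; 8,759/4,519 → 1.94 for UK→SA, 10.8 for USA→SA), PPP division,
and inflation to 2020, applied in a configurable order (default inflate
→ PPP → basket). Only the basket totals were published, so each basket
fixture carries a single aggregate item. The bundled USD inflation
series is an *implied deflator* (constant 1.065/yr) calibrated so the
one validated row (pneumonia $23,030, 2011 → $3,752) reproduces within
±2%; it is an editable fixture, not an official CPI series. Rand
figures are display-only at a single factor, default 17.35, which fits
every published result-table $/R pair; the source's own small-value
pair (gel $2.82 / R 18.85) implies ≈6.7 and is simply inconsistent —
documented, not reconciled.

## Deterministic sensitivity analysis

The RRR sweep and its gel-cost break-offs run at each swept RRR; all
other one-way rows and the extreme scenarios run at a conservative RRR
context of 0.01, where parameters bite hardest (their printed
incremental benefit 0.0004 = 0.01 × 39/931 confirms this convention).
One-way overrides touch exactly one arm post-derivation and do not
re-derive the other arm. Break-off search brackets from the base value,
widening geometrically (≤10 doublings), and solves with Brent's method
to $0.5 / 0.05 days; absence of a sign change is reported as "no
break-off in range" rather than extrapolated. The extreme scenarios
move intervention-arm pneumonia/critical-care/ventilation probabilities
and pneumonia stay lengths to one bound and the bed-day/pneumonia-cost
items to the other; the published extreme incremental benefits (0.0119,
−0.0081) identify the varied pneumonia probability as the
intervention-arm one, which is how it is implemented. Published one-way
*cost* deltas (e.g. +$21 for the critical-care stay row) are not
reproduced exactly by any leaf-level reading of the aggregate stay rows;
they are reported but only the algebraically forced incremental
benefits are asserted.

## Probabilistic sensitivity analysis

10,000 Monte-Carlo iterations by default. Count-backed probabilities
draw from Beta(events, total − events) — mean equal to the observed
proportion; degenerate all-or-nothing counts get a +0.5/+0.5 continuity
correction. Costs draw from gamma with shape 1/cv², scale mean·cv², so
the draw mean equals the base cost; the published analysis states no
cost variance, so cv defaults to 0.2, is configurable per item and is
echoed in output metadata. Stay lengths are fixed (no published
uncertainty). Draws are independent across parameters; each iteration
re-derives the intervention arm from the drawn control values at the
configured RRR, keeping the arms internally consistent (the published
intervention-arm distribution annotations are treated as describing the
deterministic derivation, not an independent sampling scheme). One root
seed spawns per-parameter substreams keyed by a stable SHA-256 hash of
the parameter name, so adding a parameter never perturbs the others'
draws and fixed-seed runs are bitwise reproducible.

The published Monte-Carlo cost means ($5,067 / $5,302) exceed the
deterministic base case by ~28%, implying unpublished skewed
hyperparameters; they are documented as non-reproducible and are not
targets. The PSA contract is distributional: degenerate specs reproduce
the base case exactly, the mean pneumonia reduction converges to
RRR × E[beta draw], CEAC values lie in [0, 1].

## Microsimulation and synthetic cohorts

`simulate_cohort` routes individual patients by independent Bernoulli
draws per node and prices them with the same pathway costing as the
analytic tree; per-patient stays default to the class means so the
simulator matches the cohort model exactly in expectation (a
gamma-stay mode exists for stress tests). It is the brute-force oracle:
at n = 200,000 the Monte-Carlo means agree with the analytic values
within 3 standard errors per arm. `synthesize_cohort_tables` produces
event/total tables by hierarchical binomial sampling (each node's
denominator is its parent's event count); feeding counts back through
the beta parameterization recovers the generating probabilities, and
over 100 replicate cohorts of 931 patients the 95% central beta
interval covers the true pneumonia probability at the expected ~95%
rate (accepted band 90–99%).

## Problem sizes and numerics

Default sizes used throughout the package and its checks: 10,000 PSA
iterations; 200,000 microsimulation patients for oracle comparisons;
100 replicate synthetic cohorts of 931 for interval coverage; WTP grid
$0–$30,000 in $250 steps (the published curve states the range but not
the step). CEAC ties (NMB exactly 0) count one half. ICERs at zero
effect are flagged (NaN when both deltas are zero, signed infinity
otherwise) rather than silently divided. All evaluation is closed-form
summation over 12 pathway templates; the PSA vectorizes the same
templates over draw arrays, so there is one arithmetic path, not two.

## Limitations

- The synthetic cohort generator emulates only the count structure the
  model consumes — no hospital clustering, covariates or inclusion
  criteria of the source cohorts — so passing recovery tests says the
  pipeline is self-consistent, not that the source estimates are
  unbiased.
- Between-parameter correlation is not modelled (none is published).
- The effectiveness evidence itself is extrapolated from cardiac
  surgery; this package reproduces the model's logic and cannot
  strengthen that evidence base.
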