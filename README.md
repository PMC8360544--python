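# mouthwash-cea

Decision-analytic cost-effectiveness model of **two doses of preoperative
chlorhexidine mouthwash versus no mouthwash** for preventing postoperative
pneumonia among adult abdominal-surgery patients, from the South African
healthcare-provider perspective over a 30-day horizon.

The package is aimed at health economists and HTA analysts who want a
reproducible, testable implementation of this model: base-case
evaluation, a pandemic (COVID-19) scenario overlay, deterministic and
probabilistic sensitivity analysis, cost-transfer utilities (market
basket, PPP, inflation), and a patient-level microsimulation that acts
as an independent cross-check of the cohort arithmetic.

## The model

A 30-day decision tree, identical in shape for both arms:

```
surgery ── pneumonia? ── critical care? ── ventilated? ── died / discharged
                     └── general ward  ─────────────────── died / discharged
```

Branch probabilities come from two prospective surgical cohorts
(event/total counts, e.g. pneumonia 39/931 in the control arm) plus a
few expert-opinion values. The intervention arm is derived from the
control arm by a relative risk reduction (RRR, base 0.3):

```
p_int = p_ctrl x (1 - RRR)
```

applied to the pneumonia probability and, among pneumonia patients, the
critical-care, ventilation and critical-care mortality probabilities;
all no-pneumonia parameters are identical across arms by assumption.

Per-patient pathway cost = procedure + (chlorhexidine if mouthwash arm)
+ (pneumonia episode if pneumonia) + mean length of stay x ward/ICU
daily rate + (ventilation episode if ventilated) + (pandemic add-on in
scenario 2), all in 2020 international dollars. Effectiveness is the
proportion of patients with pneumonia (effect 1 = no pneumonia), so the
comparison reports

```
delta_cost  = E[cost | mouthwash] - E[cost | no mouthwash]
delta_effect = p_pneu(no mouthwash) - p_pneu(mouthwash)
NMB(lambda) = lambda x delta_effect - delta_cost
ICER        = delta_cost / delta_effect   (when neither arm dominates)
```

## Worked example

```python
from mouthwash_cea import (CONTROL, INTERVENTION, compare_arms,
                           evaluate_arm, load_parameter_set)

params = load_parameter_set()          # bundled fixtures, RRR 0.3
ctrl  = evaluate_arm(params, CONTROL)
mw    = evaluate_arm(params, INTERVENTION)
ce    = compare_arms(mw, ctrl)
```

Running `python examples/basecase.py` prints:

```
no-mouthwash: cost $3,993  pneumonia proportion 0.042
mouthwash:    cost $3,705  pneumonia proportion 0.029
difference:   $-288 (R -5,000), pneumonia reduction 0.0126 -> intervention_dominates
```

The mouthwash strategy costs about $288 less per patient and produces
1.3 fewer pneumonia cases per hundred patients, so it *dominates* (is
cheaper and more effective); no ICER is reported. The `examples/`
directory holds one short script per capability (pandemic scenario,
deterministic sensitivity analysis, probabilistic analysis with CEAC,
microsimulation cross-check, currency conversion), and the
`mouthwash-cea` command exposes the same stages as `basecase`, `dsa`,
`psa`, `convert` and `simulate` subcommands writing CSV/JSON reports.

## Layout

- `src/mouthwash_cea/` — library: `parameters`, `currency`, `tree`,
  `cea`, `sensitivity`, `psa`, `microsim`, `config`/`report`/`cli`.
- `src/mouthwash_cea/data/` — editable input fixtures (probability,
  cost, stay and DSA-bound tables; scenario and conversion YAML).
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — model assumptions, parameter conventions,
  numerical choices and known limitations.
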