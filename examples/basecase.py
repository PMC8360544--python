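"""Base-case comparison: mouthwash versus no mouthwash, pandemic-free.

Loads the bundled probability/cost/stay fixtures, evaluates both arms of
the 30-day decision tree and prints the incremental results in 2020
international dollars and display Rand.
"""

from mouthwash_cea import (CONTROL, INTERVENTION, compare_arms, evaluate_arm,
                           load_parameter_set, to_display_zar)

params = load_parameter_set()  # RRR 0.3 by default
ctrl = evaluate_arm(params, CONTROL)
interv = evaluate_arm(params, INTERVENTION)
ce = compare_arms(interv, ctrl)

print(f"no-mouthwash: cost ${ctrl.expected_cost:,.0f}  "
      f"pneumonia proportion {ctrl.pneumonia_proportion:.3f}")
print(f"mouthwash:    cost ${interv.expected_cost:,.0f}  "
      f"pneumonia proportion {interv.pneumonia_proportion:.3f}")
print(f"difference:   ${ce.delta_cost:,.0f} (R {to_display_zar(ce.delta_cost):,.0f}), "
      f"pneumonia reduction {ce.delta_effect:.4f} -> {ce.classification}")
# A negative cost difference with a positive pneumonia reduction means the
# mouthwash strategy is cheaper AND more effective: it dominates.
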