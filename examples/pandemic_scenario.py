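"""Pandemic overlay: higher pneumonia risk plus a per-patient cost add-on.

Both published readings of the overlay are evaluated: the literal +1.8
percentage-point increment, and the smaller increment calibrated to the
published pandemic-scenario proportions.  Either way every patient in
both arms accrues the $254 pandemic-practices cost, and the intervention
arm is re-derived from the shifted control pneumonia probability.
"""

from mouthwash_cea import (CONTROL, INTERVENTION, CovidOverlay,
                           apply_covid_overlay, evaluate_arm,
                           evaluate_comparison, load_parameter_set)

params = load_parameter_set()
base = evaluate_comparison(params)
print(f"pandemic-free   : delta cost ${base.delta_cost:,.0f}")

for overlay in (CovidOverlay.absolute(), CovidOverlay.calibrated()):
    p2 = apply_covid_overlay(params, overlay)
    ce = evaluate_comparison(p2)
    props = (evaluate_arm(p2, CONTROL).pneumonia_proportion,
             evaluate_arm(p2, INTERVENTION).pneumonia_proportion)
    print(f"{overlay.mode:15s}: delta cost ${ce.delta_cost:,.0f}, proportions "
          f"{props[0]:.3f} vs {props[1]:.3f} ({ce.classification})")
# More pneumonia to prevent means more saving: the cost difference is
# strictly more negative than in the pandemic-free base case.
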