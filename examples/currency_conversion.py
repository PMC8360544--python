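"""Cost transfer: market-basket index, inflation, PPP, Rand display.

Rebuilds the UK-South-Africa basket index from the published basket
totals and audits the conversion chain for the pneumonia-episode cost.
"""

from mouthwash_cea import (adjust_cost, basket_index, load_conversion_context,
                           load_parameter_set, to_display_zar)

baskets, ctx = load_conversion_context()
index = basket_index(baskets["uk"], baskets["south_africa"])
print(f"UK basket ${baskets['uk'].total:,.0f} / SA basket "
      f"${baskets['south_africa'].total:,.0f} -> index {index:.2f}")

params = load_parameter_set()
item = params.costs["pneumonia_episode"]
result = adjust_cost(item, ctx)
print(f"\n{item.name}: ${item.raw_value:,.0f} ({item.source_year} "
      f"{item.source_currency}) -> ${result.value:,.0f} "
      f"(published adjusted ${item.adjusted_2020_intl_usd:,.0f})")
for step in result.chain:
    print("  ", step)

print(f"\ndisplay: $-283 -> R {to_display_zar(-283):,.0f}")
# The audit chain records every factor applied, so a reviewer can see
# exactly how a source-currency cost became a 2020 international-dollar
# value at the South African price level.
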