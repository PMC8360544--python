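# Market-basket totals and conversion factors for expressing costs in
# 2020 international dollars (South African price level).
#
# Only the basket totals were published for the UK and South African
# baskets; each basket is therefore carried as a single aggregate item.
# The USD inflation series is an implied deflator calibrated so that the
# one published cross-check (pneumonia episode, $23,030 in 2011 USD,
# USA-SA index 10.8 -> $3,752) reproduces; it is editable.
baskets:
  uk:
    setting: UK
    items:
      - [healthcare services basket, 8759.0]
  south_africa:
    setting: South Africa
    items:
      - [healthcare services basket, 4519.0]
basket_indices:
  UK: 1.94
  USA: 10.8
  South Africa: 1.0
ppp_per_intl_usd:
  USD: 1.0
  GBP: 0.7
inflation:
  USD:
    2009: 1.065
    2010: 1.065
    2011: 1.065
    2012: 1.065
    2013: 1.065
    2014: 1.065
    2015: 1.065
    2016: 1.065
    2017: 1.065
    2018: 1.065
    2019: 1.065
    2020: 1.065
  GBP:
    2016: 1.02
    2017: 1.02
    2018: 1.02
    2019: 1.02
    2020: 1.02
display_zar_per_intl_usd: 17.35
order: [inflate, ppp, basket]
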