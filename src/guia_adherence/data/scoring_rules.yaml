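# Canonical encoding of the ten adherence components of the Guia Alimentar
# marker index, in both threshold variants.
#
# Each component awards one point when the predicate `<marker> <op> <threshold>`
# holds. Markers are canonical weekly day-counts (0-7), except `upf_sum`,
# the count of ultra-processed items consumed on the previous day (0-13).
# "ideal" is the more restricted variant (daily unprocessed staples, zero
# ultra-processed exposure); "possible" is the less restricted variant
# (ultra-processed exposure tolerated up to twice a week, previous-day
# ultra-processed sum at or below 3 items).
ideal:
  "1.1": {marker: beans_days, op: ge, threshold: 7}
  "1.2": {marker: fruit_days, op: ge, threshold: 7}
  "1.3": {marker: vegetables_days, op: ge, threshold: 7}
  "2.1": {marker: soda_days, op: le, threshold: 0}
  "2.2": {marker: sweets_days, op: le, threshold: 0}
  "2.3": {marker: upf_sum, op: le, threshold: 0}
  "3.1": {marker: breakfast_days, op: ge, threshold: 7}
  "3.2": {marker: family_meal_days, op: ge, threshold: 7}
  "3.3": {marker: screen_eating_days, op: le, threshold: 0}
  "4.1": {marker: fastfood_days, op: le, threshold: 0}
possible:
  "1.1": {marker: beans_days, op: ge, threshold: 7}
  "1.2": {marker: fruit_days, op: ge, threshold: 7}
  "1.3": {marker: vegetables_days, op: ge, threshold: 7}
  "2.1": {marker: soda_days, op: le, threshold: 2}
  "2.2": {marker: sweets_days, op: le, threshold: 2}
  "2.3": {marker: upf_sum, op: le, threshold: 3}
  "3.1": {marker: breakfast_days, op: ge, threshold: 7}
  "3.2": {marker: family_meal_days, op: ge, threshold: 7}
  "3.3": {marker: screen_eating_days, op: le, threshold: 2}
  "4.1": {marker: fastfood_days, op: le, threshold: 2}
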