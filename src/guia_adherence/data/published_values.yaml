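# Reference estimates from the source publication's PeNSE 2019 analysis,
# against which `guia reproduce` compares a run on the real microdata.
# Percentages are printed percentages; PRs are final-model adjusted
# prevalence ratios (references: urban / South / capital / very unhappy with
# body / very bad self-rated health).
retained_pct:
  value: 96.2
  unit: percent
  note: valid records / initial sample (153,153 of 159,245)
weighted_population:
  value: 15192972
  unit: adolescents
  note: design-weighted total represented by the valid records
full_adherence_possible_pct:
  value: 0.4
  unit: percent
  note: possible-variant score 10, design-weighted prevalence
full_adherence_ideal_pct:
  value: 0.0
  unit: percent
  note: ideal-variant score 10, design-weighted prevalence
pr_rural:
  value: 1.91
pr_region_southeast:
  value: 1.53
pr_region_north:
  value: 1.16
pr_region_midwest:
  value: 2.29
pr_region_northeast:
  value: 1.92
pr_out_of_capital:
  value: 1.33
pr_body_unhappy:
  value: 0.61
pr_body_indifferent:
  value: 0.92
pr_body_happy:
  value: 1.76
pr_body_very_happy:
  value: 2.72
pr_health_bad:
  value: 6.11
pr_health_regular:
  value: 1.45
pr_health_good:
  value: 1.68
pr_health_very_good:
  value: 3.87
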