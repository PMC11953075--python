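# Dutch population-based biennial screening base scenario.
label: nl_base
cohort_size: 100000
iterations: 10
seed: 1
max_age: 100
life_table:
  bands: nl_mortality_bands.csv
onset: nl_onset.csv
progression: nl_progression.csv
regression:
  g1: 0.0488
  g2: 0.0488
  g3: 0.0488
clinical: 0.05
screening:
  start_age: 50
  end_age: 74
  interval: 2
  participation: 0.76
  sensitivity: 0.86
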