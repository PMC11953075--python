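# UK screening setting: triennial rounds at ages 50-71, UK mortality.
# Participation and sensitivity are inherited from the Dutch base scenario
# (not separately published for this setting); the shipped mortality table is
# a synthetic stand-in -- see uk_mortality_bands_synthetic.csv.
label: uk_base
cohort_size: 100000
iterations: 10
seed: 1
max_age: 100
life_table:
  bands: uk_mortality_bands_synthetic.csv
onset: nl_onset.csv
progression: nl_progression.csv
regression:
  g1: 0.0488
  g2: 0.0488
  g3: 0.0488
clinical: 0.05
screening:
  start_age: 50
  end_age: 71
  interval: 3
  participation: 0.76
  sensitivity: 0.86
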