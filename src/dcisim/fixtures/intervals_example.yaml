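# Illustrative +/-10%-style uncertainty intervals for sensitivity analysis.
# Table-valued parameters (onset, progression, mortality) vary through a
# single table-wide multiplier with base value 1.0.
intervals:
  - {parameter: onset.scale, low: 0.9, high: 1.1}
  - {parameter: progression.scale, low: 0.9, high: 1.1}
  - {parameter: mortality.scale, low: 0.9, high: 1.1}
  - {parameter: regression.value, low: 0.04392, high: 0.05368}
  - {parameter: clinical.value, low: 0.045, high: 0.055}
  - {parameter: screening.participation, low: 0.684, high: 0.836}
  - {parameter: screening.sensitivity, low: 0.774, high: 0.946}
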