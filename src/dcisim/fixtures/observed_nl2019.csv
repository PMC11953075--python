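# Observed Dutch screen-detection rates of DCIS per 1,000 screened women (2019 registry).
stratum,observed
age_50-54,1.6
age_55-59,1.1
age_60-64,1.0
age_65-69,1.5
age_70-74,1.9
grade_1,0.2
grade_2,0.5
grade_3,0.6
total,1.38
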