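# Observed UK (NHS, 2021) screen-detection rates of DCIS per 1,000 screened women.
stratum,observed
age_50-54,1.6
age_55-59,1.5
age_60-64,1.8
age_65-69,1.9
age_70-74,2.4
total,1.7
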