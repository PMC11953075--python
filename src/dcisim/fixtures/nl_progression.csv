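# DCIS -> IBC progression probability (P4) by age band and grade, fraction per year.
lower,upper,g1,g2,g3
0,19,0.000,0.000,0.000
20,54,0.087,0.137,0.159
55,100,0.073,0.115,0.134
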