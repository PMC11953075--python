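# Dutch all-cause female death probability (P1), per-band endpoint ranges,
# units 1e-2 per year; endpoints pinned to band first/last age, log-linear in between.
lower,upper,first,last
0,0,0.324,0.324
1,9,0.050,0.008
10,19,0.008,0.018
20,29,0.019,0.027
30,39,0.032,0.064
40,49,0.070,0.201
50,59,0.233,0.496
60,69,0.538,1.137
70,79,1.210,3.441
80,89,3.972,12.55
90,99,14.33,32.30
100,100,100.0,100.0
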