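# DCIS onset probability (P2) by age band and grade, units 1e-3 per year.
lower,upper,g1,g2,g3
0,19,0.0000,0.0000,0.0000
20,24,0.0016,0.0003,0.0013
25,29,0.0019,0.0043,0.0075
30,34,0.0017,0.0127,0.0199
35,39,0.0119,0.0221,0.0406
40,44,0.0213,0.0516,0.0526
45,48,0.0398,0.0600,0.0665
49,54,0.2095,0.3105,0.3250
55,59,0.0859,0.1805,0.2558
60,64,0.0948,0.2396,0.3002
65,69,0.1016,0.2674,0.2857
70,75,0.1540,0.3556,0.3703
76,79,0.0307,0.0630,0.0491
80,94,0.0361,0.0585,0.0452
95,100,0.0000,0.0000,0.0000
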