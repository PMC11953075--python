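# SYNTHETIC stand-in for a UK 2019 female all-cause life table, per-band
# endpoint ranges in units 1e-2 per year.  Values are plausible national-
# life-table magnitudes, not an official publication; replace with the
# authoritative per-age table (life_table: {ages: ...}) for real analyses.
lower,upper,first,last
0,0,0.380,0.380
1,9,0.030,0.008
10,19,0.008,0.019
20,29,0.022,0.030
30,39,0.038,0.076
40,49,0.086,0.220
50,59,0.255,0.550
60,69,0.610,1.330
70,79,1.480,4.050
80,89,4.750,13.80
90,99,15.70,33.80
100,100,100.0,100.0
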