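# Serum albumin concentration relative to the 30-year-old adult reference,
# literature-informed age profile (mild hypoalbuminemia in young children and
# in the elderly). Linear interpolation in age; flat outside the grid.
# Columns: age_years,ratio_to_adult
age_years,ratio_to_adult
0,0.78
1,0.90
2,0.93
5,0.96
10,0.99
15,1.00
40,1.00
60,0.97
70,0.95
100,0.92
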