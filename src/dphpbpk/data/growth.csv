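# Median body weight (kg) and height (cm) by age and sex, CDC/WHO-style growth
# reference medians; adult values are ICRP-style reference adults.
# Columns: age_years,sex,weight_kg,height_cm
age_years,sex,weight_kg,height_cm
2,male,12.5,87
3,male,14.3,95
4,male,16.3,102
5,male,18.4,109
6,male,20.7,115
8,male,25.8,128
10,male,32.0,138
12,male,40.0,149
14,male,51.0,163
15,male,56.0,169
16,male,61.0,173
18,male,68.0,176
25,male,73.0,176
30,male,73.0,176
40,male,75.0,176
50,male,76.0,175
60,male,75.0,174
70,male,73.0,172
80,male,70.0,170
100,male,65.0,167
2,female,12.0,86
3,female,13.9,94
4,female,15.9,101
5,female,17.9,108
6,female,20.0,114
8,female,25.4,127
10,female,32.5,138
12,female,41.5,151
14,female,49.0,159
15,female,52.0,161
16,female,54.0,162
18,female,57.0,163
25,female,60.0,163
30,female,60.0,163
40,female,62.0,163
50,female,64.0,162
60,female,64.0,161
70,female,62.0,159
80,female,59.0,157
100,female,55.0,155
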