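# Organ volume as fraction of body weight (density ~1 kg/L assumed), by age.
# Values assembled from ICRP-style reference anatomy (adult male/female) and
# pediatric reference organ masses; linearly interpolated in age between grid
# rows, constant above age 30. Pediatric rows (ages 2-10) are sex-shared.
# The 'rest' compartment is a lumped remainder tissue.
# Columns: age_years,organ,frac_male,frac_female
age_years,organ,frac_male,frac_female
2,lung,0.0128,0.0128
2,brain,0.0880,0.0880
2,heart,0.0056,0.0056
2,kidney,0.0072,0.0072
2,liver,0.0344,0.0344
2,gut,0.0240,0.0240
2,spleen,0.0032,0.0032
2,stomach,0.0030,0.0030
2,muscle,0.2000,0.2000
2,skin,0.0360,0.0360
2,adipose,0.2240,0.2240
2,bone,0.1360,0.1360
2,gonads,0.0002,0.0002
2,rest,0.0400,0.0400
2,arterial_blood,0.0216,0.0216
2,venous_blood,0.0504,0.0504
5,lung,0.0114,0.0114
5,brain,0.0707,0.0707
5,heart,0.0049,0.0049
5,kidney,0.0060,0.0060
5,liver,0.0310,0.0310
5,gut,0.0245,0.0245
5,spleen,0.0027,0.0027
5,stomach,0.0033,0.0033
5,muscle,0.2450,0.2450
5,skin,0.0353,0.0353
5,adipose,0.1850,0.1850
5,bone,0.1410,0.1410
5,gonads,0.0002,0.0002
5,rest,0.0400,0.0400
5,arterial_blood,0.0228,0.0228
5,venous_blood,0.0532,0.0532
10,lung,0.0109,0.0109
10,brain,0.0438,0.0438
10,heart,0.0044,0.0044
10,kidney,0.0056,0.0056
10,liver,0.0259,0.0259
10,gut,0.0219,0.0219
10,spleen,0.0025,0.0025
10,stomach,0.0028,0.0028
10,muscle,0.2810,0.2810
10,skin,0.0375,0.0375
10,adipose,0.1720,0.1780
10,bone,0.1560,0.1500
10,gonads,0.0003,0.0003
10,rest,0.0400,0.0400
10,arterial_blood,0.0225,0.0225
10,venous_blood,0.0525,0.0525
15,lung,0.0075,0.0078
15,brain,0.0254,0.0270
15,heart,0.0041,0.0041
15,kidney,0.0045,0.0047
15,liver,0.0232,0.0250
15,gut,0.0170,0.0180
15,spleen,0.0021,0.0022
15,stomach,0.0021,0.0022
15,muscle,0.3390,0.2700
15,skin,0.0393,0.0385
15,adipose,0.1610,0.2400
15,bone,0.1430,0.1300
15,gonads,0.0004,0.0002
15,rest,0.0400,0.0400
15,arterial_blood,0.0225,0.0220
15,venous_blood,0.0525,0.0512
30,lung,0.0076,0.0078
30,brain,0.0199,0.0217
30,heart,0.0045,0.0042
30,kidney,0.0042,0.0046
30,liver,0.0246,0.0233
30,gut,0.0164,0.0183
30,spleen,0.0021,0.0022
30,stomach,0.0021,0.0023
30,muscle,0.3970,0.2920
30,skin,0.0450,0.0383
30,adipose,0.1990,0.3200
30,bone,0.1430,0.1283
30,gonads,0.0005,0.0002
30,rest,0.0400,0.0400
30,arterial_blood,0.0230,0.0215
30,venous_blood,0.0537,0.0502
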