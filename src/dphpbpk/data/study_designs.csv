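# Study designs of the twelve observed concentration-time profiles (cohort
# demographics and dosing). age_ref/weight_ref are cohort midpoints used for
# the deterministic reference prediction of each scenario; weight_ref empty
# means "growth-table default for (age_ref, sex_ref)". female_fraction 56.25
# in the source table is ambiguous and stored verbatim (as 0.5625).
# Columns: label,cohort,route,formulation,dose,per_kg,age_min,age_max,age_ref,sex_ref,weight_ref,female_fraction
label,cohort,route,formulation,dose,per_kg,age_min,age_max,age_ref,sex_ref,weight_ref,female_fraction
iv_50,young_adults,iv_bolus,solution,50,0,26,41,33.5,male,,0.40
po_25_young_men,young_adults,po,lint80,25,0,24.6,36.2,30.4,male,73.9,0.0
po_25_young_women,young_adults,po,lint80,25,0,27,31.8,29.4,female,65.4,1.0
po_50_young,young_adults,po,lint80,50,0,26,41,33.5,male,,0.40
po_87.9_young,young_adults,po,lint80,87.9,0,21.1,41.9,31.5,male,70.3,0.50
po_25_elderly_men,elderly_adults,po,lint80,25,0,62.5,66.1,64.3,male,71.9,0.0
po_25_elderly_women,elderly_adults,po,lint80,25,0,68.9,71.3,70.1,female,69.2,1.0
po_86_elderly,elderly_adults,po,lint80,86,0,65.1,73.7,69.4,male,71.0,0.50
po_0.556_children,children,po,lint80,0.556,1,2.76,4.84,3.8,male,17.3,0.38
po_0.807_children,children,po,lint80,0.807,1,6.61,9.99,8.3,male,29.9,0.5625
po_1.25_children,children,po,lint80,1.25,1,7.2,10.6,8.9,male,31.6,0.50
po_0.93_adolescents,adolescents,po,lint80,0.93,1,12.75,16.45,14.6,male,55.3,0.50
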