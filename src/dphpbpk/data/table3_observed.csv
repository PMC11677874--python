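# Transcribed predicted/observed NCA summary fixture: per-scenario Cmax
# (ng/mL), AUC0-inf (ng*h/mL) and CL (L/h, or L/h/kg for per-kg-dosed
# pediatric rows) with the published ratios for cross-checking.
# Columns: row,label,cohort,parameter,predicted,observed,printed_ratio,per_kg
row,label,cohort,parameter,predicted,observed,printed_ratio,per_kg
1,iv_50,young_adults,cmax,150.54,251.1,0.6,0
1,iv_50,young_adults,auc_0_inf,841.09,565.97,1.48,0
1,iv_50,young_adults,clearance,59.44,88.34,0.67,0
2,po_25_young_men,young_adults,cmax,22.95,29.65,0.78,0
2,po_25_young_men,young_adults,auc_0_inf,191.45,190.25,1,0
2,po_25_young_men,young_adults,clearance,130.58,131.4,0.99,0
3,po_25_young_women,young_adults,cmax,29.75,30.28,0.98,0
3,po_25_young_women,young_adults,auc_0_inf,256.4,212.39,1.2,0
3,po_25_young_women,young_adults,clearance,97.5,117.7,0.82,0
4,po_50_young,young_adults,cmax,51,68.42,0.75,0
4,po_50_young,young_adults,auc_0_inf,484.36,507.32,0.95,0
4,po_50_young,young_adults,clearance,103.22,98.55,1.04,0
5,po_87.9_young,young_adults,cmax,83.44,101.62,0.82,0
5,po_87.9_young,young_adults,auc_0_inf,828.82,1131.12,0.73,0
5,po_87.9_young,young_adults,clearance,106.05,77.71,1.36,0
6,po_25_elderly_men,elderly_adults,cmax,24.17,22.45,1.07,0
6,po_25_elderly_men,elderly_adults,auc_0_inf,209.02,214.22,0.97,0
6,po_25_elderly_men,elderly_adults,clearance,119.6,116.69,1.02,0
7,po_25_elderly_women,elderly_adults,cmax,28.04,23.19,1.2,0
7,po_25_elderly_women,elderly_adults,auc_0_inf,275.78,188.08,1.46,0
7,po_25_elderly_women,elderly_adults,clearance,90.64,132.92,0.68,0
8,po_86_elderly,elderly_adults,cmax,82.28,165.02,0.5,0
8,po_86_elderly,elderly_adults,auc_0_inf,917.97,1827.5,0.5,0
8,po_86_elderly,elderly_adults,clearance,93.68,47.05,1.99,0
9,po_0.556_children,children,cmax,44.32,44.14,1,1
9,po_0.556_children,children,auc_0_inf,339.38,329.31,1.03,1
9,po_0.556_children,children,clearance,1.73,1.79,0.96,1
10,po_0.807_children,children,cmax,67.52,74.52,0.9,1
10,po_0.807_children,children,auc_0_inf,525.04,580.4,0.9,1
10,po_0.807_children,children,clearance,1.54,1.39,1.1,1
11,po_1.25_children,children,cmax,94.95,81.16,1.16,1
11,po_1.25_children,children,auc_0_inf,823.91,467.25,1.76,1
11,po_1.25_children,children,clearance,1.51,2.67,0.56,1
12,po_0.93_adolescents,adolescents,cmax,74.16,89.1,0.83,1
12,po_0.93_adolescents,adolescents,auc_0_inf,649.49,839.07,0.77,1
12,po_0.93_adolescents,adolescents,clearance,1.39,1.07,1.29,1
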