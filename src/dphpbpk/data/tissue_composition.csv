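# Tissue composition for Rodgers-Rowland partition-coefficient prediction,
# literature values (fractional volumes of extracellular/intracellular water,
# neutral lipid, neutral phospholipid; acidic phospholipid concentration in
# mg/g tissue). 'stomach' and 'rest' are assigned gut-like / lean-average
# compositions; 'blood_cells' is the erythrocyte row used to back-calculate
# the acidic-phospholipid association constant from the blood:plasma ratio.
# Columns: tissue,f_ew,f_iw,f_nl,f_np,ap_mg_g
tissue,f_ew,f_iw,f_nl,f_np,ap_mg_g
lung,0.336,0.446,0.0220,0.0130,3.91
brain,0.162,0.620,0.0390,0.0015,0.40
heart,0.320,0.456,0.0140,0.0110,2.25
kidney,0.273,0.483,0.0120,0.0240,5.03
liver,0.161,0.573,0.0140,0.0240,4.56
gut,0.282,0.475,0.0380,0.0125,2.41
spleen,0.207,0.579,0.0077,0.0113,3.18
stomach,0.268,0.480,0.0320,0.0110,2.41
muscle,0.118,0.630,0.0100,0.0072,1.53
skin,0.382,0.291,0.0600,0.0044,1.32
adipose,0.135,0.017,0.8530,0.0016,0.40
bone,0.100,0.346,0.0170,0.0017,0.67
gonads,0.255,0.525,0.0048,0.0157,0.89
rest,0.200,0.500,0.0200,0.0080,1.60
blood_cells,0.000,0.603,0.0017,0.0029,0.50
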