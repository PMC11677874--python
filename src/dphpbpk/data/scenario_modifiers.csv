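# Packaged physiology modifiers for impaired-population scenarios, editable
# defaults following published CKD / Child-Pugh cirrhosis scaler conventions:
# CKD stages scale GFR (~0.5/0.25/0.08 of normal); end-stage disease adds
# dialysis-associated hypoalbuminemia. Child-Pugh grades reduce hepatic blood
# flow, functional CYP expression and albumin while increasing portosystemic
# shunting from A to C.
# Columns: name,gfr_mult,albumin_mult,hepatic_flow_mult,cyp_mult,shunt_fraction
name,gfr_mult,albumin_mult,hepatic_flow_mult,cyp_mult,shunt_fraction
healthy,1.0,1.0,1.0,1.0,0.0
ckd3,0.5,1.0,1.0,1.0,0.0
ckd4,0.25,1.0,1.0,1.0,0.0
ckd5,0.08,0.80,1.0,1.0,0.0
cp_a,1.0,0.90,0.85,0.70,0.10
cp_b,1.0,0.75,0.65,0.45,0.25
cp_c,1.0,0.60,0.45,0.25,0.45
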