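# Diphenhydramine drug-parameter config (default fixture).
# Physicochemistry, binding, permeability and enzyme kinetics are compiled
# clinical/in-vitro literature values; enzyme abundances (pmol per mg of
# microsomal protein) and the blood:plasma ratio are literature-typical
# packaged defaults, user-overridable.
name: diphenhydramine
molecular_weight: 255.36        # g/mol
log_p: 3.27
pka: 8.98                       # monoprotic base
water_solubility_mg_ml: 3.06    # at pH 7.00
fu_plasma_adult: 0.18
binding_protein: albumin
caco2_permeability_cm_s: 5.43e-4
specific_organ_permeability_cm_min: 0.19   # informational; perfusion-limited model
renal_clearance_l_h_kg: 0.01
blood_to_plasma_ratio: 1.10
# Global scalar applied to hepatic intrinsic clearance, fitted once on the
# adult IV 50 mg run against the IV-route reference clearance (59.44 L/h)
# and reused unchanged everywhere (see docs/methods.md).
calibration_factor: 5.799
enzyme_kinetics:
  - enzyme: CYP1A2
    vmax_pmol_min_pmol: 14.0
    km_um: 295.0
    abundance_pmol_mg: 52.0
  - enzyme: CYP2C9
    vmax_pmol_min_pmol: 4.43
    km_um: 134.0
    abundance_pmol_mg: 73.0
  - enzyme: CYP2C19
    vmax_pmol_min_pmol: 11.0
    km_um: 55.7
    abundance_pmol_mg: 14.0
  - enzyme: CYP2D6
    vmax_pmol_min_pmol: 2.38
    km_um: 1.12
    abundance_pmol_mg: 8.0
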