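# Regional blood flow as fraction of cardiac output (ICRP-style resting adult).
# liver receives 'liver' (hepatic arterial) plus the venous outflow of gut,
# spleen and stomach (portal vein). The 'rest' fraction is assigned the exact
# remainder at build time so organ flows always sum to cardiac output.
# Columns: organ,frac_co
organ,frac_co
brain,0.1200
heart,0.0400
kidney,0.1900
liver,0.0650
gut,0.1500
spleen,0.0300
stomach,0.0100
muscle,0.1700
skin,0.0500
adipose,0.0500
bone,0.0500
gonads,0.0005
rest,0.0745
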