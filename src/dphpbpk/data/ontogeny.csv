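# Hepatic CYP ontogeny: fraction of adult expression
#   f(age) = birth_fraction + (1 - birth_fraction) * age^h / (age^h + tm50^h)
# Hill-curve parameters chosen from published ontogeny profiles: CYP2D6 and
# CYP2C9 near-adult within the first year, CYP2C19 intermediate, CYP1A2 the
# slowest to mature.
# Columns: enzyme,tm50_years,hill,birth_fraction
enzyme,tm50_years,hill,birth_fraction
CYP1A2,1.20,1.4,0.03
CYP2C9,0.15,1.3,0.10
CYP2C19,0.50,1.2,0.10
CYP2D6,0.29,1.3,0.05
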