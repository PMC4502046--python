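variable,benign,malignant,p_value
age_mean_yr,57.2,67,0.074
age_sd_yr,22,11,
female,6,24,1
male,14,50,
central,9,46,0.13
peripheral,11,28,
size_mean_mm,51.1,48.1,0.578
size_sd_mm,17.4,21.9,
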