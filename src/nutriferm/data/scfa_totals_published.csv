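cohort,product,total_mM,total_sd_mM
normal_weight,Control,35.08,1.71
normal_weight,ST,40.63,1.81
normal_weight,RT,53.03,6.36
normal_weight,SH,35.03,6.94
normal_weight,RH,42.90,3.03
obese,Control,28.83,8.29
obese,ST,29.47,3.25
obese,RT,36.13,4.61
obese,SH,29.39,1.75
obese,RH,34.11,1.61
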