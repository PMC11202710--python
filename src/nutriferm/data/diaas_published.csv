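product_id,diaas_mean,diaas_sd,limiting,age_group
ST,66.68,4.39,SAA,older_child_adolescent_adult
RT,86.24,3.24,Val,older_child_adolescent_adult
SH,57.14,24.59,SAA,older_child_adolescent_adult
RH,90.05,0.91,Val,older_child_adolescent_adult
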