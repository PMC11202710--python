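cohort,product,acid,mean_mM,sd_mM,n
normal_weight,Control,acetic,20.60,0.78,2
normal_weight,Control,propionic,10.38,0.85,2
normal_weight,Control,butyric,4.10,1.64,2
normal_weight,ST,acetic,24.65,0.82,2
normal_weight,ST,propionic,12.07,0.76,2
normal_weight,ST,butyric,3.92,0.22,2
normal_weight,RT,acetic,34.13,5.62,2
normal_weight,RT,propionic,14.80,0.28,2
normal_weight,RT,butyric,4.10,0.46,2
normal_weight,SH,acetic,25.71,4.53,2
normal_weight,SH,propionic,5.72,2.00,2
normal_weight,SH,butyric,3.60,0.40,2
normal_weight,RH,acetic,26.46,1.03,2
normal_weight,RH,propionic,12.32,1.54,2
normal_weight,RH,butyric,4.13,0.46,2
obese,Control,acetic,18.66,1.49,2
obese,Control,propionic,7.38,5.78,2
obese,Control,butyric,2.79,1.02,2
obese,ST,acetic,21.30,0.43,2
obese,ST,propionic,3.46,4.89,2
obese,ST,butyric,4.71,2.07,2
obese,RT,acetic,31.65,2.16,2
obese,RT,propionic,1.31,1.85,2
obese,RT,butyric,3.17,0.60,2
obese,SH,acetic,25.41,1.36,2
obese,SH,propionic,1.67,1.14,2
obese,SH,butyric,2.30,0.76,2
obese,RH,acetic,27.84,0.57,2
obese,RH,propionic,2.49,0.36,2
obese,RH,butyric,3.78,2.54,2
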