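amino_acid,ST,RT,SH,RH
Asp,0.83 ± 0.14,0.88 ± 0.21,0.79 ± 0.12,0.98 ± 0.18
Ser,0.49 ± 0.01,0.51 ± 0.00,0.51 ± 0.04,0.54 ± 0.01
Glu,1.33 ± 0.19,1.42 ± 0.29,1.32 ± 0.20,1.58 ± 0.23
Gly,0.53 ± 0.02,0.66 ± 0.02,0.92 ± 0.05,0.70 ± 0.07
Arg,0.84 ± 0.04,0.98 ± 0.02,0.97 ± 0.02,1.02 ± 0.05
Ala,0.50 ± 0.03,0.61 ± 0.03,0.60 ± 0.06,0.66 ± 0.10
Pro,0.42 ± 0.03,0.46 ± 0.02,0.62 ± 0.03,0.52 ± 0.07
His,0.44 ± 0.05,0.44 ± 0.09,0.52 ± 0.07,0.54 ± 0.07
Thr,0.54 ± 0.03,0.56 ± 0.21,0.61 ± 0.36,0.62 ± 0.14
Lys,0.63 ± 0.01,0.80 ± 0.01,0.63 ± 0.04,0.87 ± 0.04
Phe,0.65 ± 0.01,0.54 ± 0.06,0.71 ± 0.10,0.59 ± 0.04
Tyr,0.51 ± 0.08,0.42 ± 0.02,0.57 ± 0.03,0.46 ± 0.14
Met,0.35 ± 0.01,0.67 ± 0.02,0.64 ± 0.05,0.64 ± 0.00
Cys,0.13 ± 0.14,0.21 ± 0.19,0.20 ± 0.11,0.20 ± 0.19
Trp,0.21 ± 0.01,0.23 ± 0.04,0.22 ± 0.05,0.23 ± 0.01
Ile,0.48 ± 0.01,0.50 ± 0.03,0.50 ± 0.08,0.55 ± 0.03
Leu,0.80 ± 0.09,0.86 ± 0.03,0.86 ± 0.04,0.94 ± 0.13
Val,0.47 ± 0.01,0.50 ± 0.02,0.51 ± 0.01,0.57 ± 0.02
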