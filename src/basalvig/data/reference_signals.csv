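scope,drug,n,ror,ror_lo,ror_hi,prr,chi2,ebgm,eb05,ic,ic025
overall_ocular,insulin_degludec,156,1.51,1.39,1.63,1.49,100.95,1.49,1.38,0.58,0.46
overall_ocular,insulin_detemir,249,2.10,1.97,2.23,2.05,602.18,2.05,1.93,1.04,0.95
overall_ocular,insulin_glargine,5380,3.60,3.54,3.67,3.43,22943.90,3.40,3.34,1.76,1.74
visual_impairment,insulin_degludec,156,4.19,3.58,4.91,4.17,375.63,4.16,3.56,2.06,1.80
visual_impairment,insulin_detemir,249,4.83,4.27,5.48,4.80,748.25,4.79,4.23,2.26,2.05
visual_impairment,insulin_glargine,5380,15.21,14.79,15.63,14.81,66084.38,14.15,13.76,3.82,3.78
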