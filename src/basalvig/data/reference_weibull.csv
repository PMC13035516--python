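drug,n,median_days,median_band_lo,median_band_hi,tto_min,tto_max,shape,shape_lo,shape_hi,scale,scale_lo,scale_hi,failure_type
insulin_degludec,156,23.6,1.0,219.8,1,821,0.4,0.34,0.79,58.47,8.54,232.50,early
insulin_detemir,249,38.5,1.0,732.5,1,4119,0.31,0.27,0.48,127.54,9.64,860.40,early
insulin_glargine,5380,175.1,2.8,1177.5,1,5841,0.44,0.40,0.51,401.13,287.53,596.76,early
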