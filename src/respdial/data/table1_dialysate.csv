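quantity,normal_plasma_low,normal_plasma_high,dialysate
ph,7.35,7.45,10.0
na_mmol_per_L,136,145,134
k_mmol_per_L,3.5,5.0,3.5
ca_mmol_per_L,2.2,2.6,0
mg_mmol_per_L,0.8,1.2,1.0
cl_mmol_per_L,98,106,116
cl_final_mmol_per_L,,,135.6
phosphate_mmol_per_L,2.0,4.5,0.5
lactate_mmol_per_L,,2.0,3.0
hco3_mmol_per_L,22,26,0
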