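# chromophore: mu_a_water
# unit: mm^-1
# provenance: synthetic anchor table approximating Hale & Querry pure-water absorption
wavelength_nm,mu_a
400,5.8e-05
450,2.9e-05
500,2.5e-05
550,4.5e-05
600,0.00023
650,0.00032
700,0.0006
750,0.00262
800,0.00206
850,0.00433
900,0.00679
920,0.012
940,0.0267
960,0.039
975,0.045
980,0.043
1000,0.0363
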