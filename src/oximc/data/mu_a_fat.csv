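# chromophore: mu_a_fat
# unit: mm^-1
# provenance: synthetic anchor table approximating van Veen soybean-oil fat absorption
wavelength_nm,mu_a
400,0.0125
420,0.011
450,0.006
500,0.0025
550,0.0012
600,0.0008
650,0.00058
700,0.0007
750,0.0011
800,0.0009
850,0.0012
880,0.0025
900,0.004
920,0.009
930,0.011
940,0.009
950,0.006
960,0.0048
980,0.0042
1000,0.0038
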