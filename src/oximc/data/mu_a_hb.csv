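# chromophore: mu_a_hb
# unit: mm^-1
# provenance: synthetic anchor table approximating Prahl deoxyhemoglobin extinction, whole blood at 150 g/L, MW 64500
wavelength_nm,mu_a
400,119.593
410,162.793
415,187.453
420,221.345
430,283.108
440,221.345
450,115.769
460,60.3793
470,34.1572
480,22.2245
490,16.2817
500,13.0489
510,11.395
520,11.0565
530,12.2134
540,24.9538
550,27.9981
555,28.6065
560,28.0302
570,24.1397
576,20.9948
580,19.8272
590,14.9963
600,7.86073
610,5.0575
620,3.48663
633,2.64042
640,2.3271
655,1.91095
660,1.72832
670,1.49695
680,1.28914
690,1.09848
700,0.960833
710,0.824795
720,0.734818
730,0.590211
740,0.642698
750,0.752492
760,0.894421
770,0.703218
780,0.60842
790,0.492735
800,0.408113
810,0.384547
820,0.371158
840,0.371158
860,0.374907
880,0.388832
900,0.407577
920,0.390974
940,0.371158
960,0.348128
980,0.33206
1000,0.326705
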