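# chromophore: mu_a_hbo2
# unit: mm^-1
# provenance: synthetic anchor table approximating Prahl oxyhemoglobin extinction, whole blood at 150 g/L, MW 64500
wavelength_nm,mu_a
400,142.589
410,257.272
415,279.659
420,257.079
430,131.792
440,54.9399
450,33.6431
460,23.8312
470,17.7867
480,14.2625
490,12.5262
500,11.2108
510,10.7309
520,13.0618
530,21.3997
540,28.5122
550,23.0386
555,19.2809
560,17.7867
570,24.3154
576,29.149
580,26.8348
590,8.83709
600,1.71386
610,0.806586
620,0.504518
633,0.326705
640,0.236727
655,0.192809
660,0.171386
670,0.157461
680,0.148356
690,0.14782
700,0.155319
710,0.168173
720,0.186382
730,0.208877
740,0.238869
750,0.277431
760,0.313851
770,0.348128
780,0.380263
790,0.39633
800,0.437034
810,0.462742
820,0.490593
840,0.547364
860,0.584855
880,0.618061
900,0.641627
920,0.645911
940,0.650196
960,0.642698
980,0.637342
1000,0.631986
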