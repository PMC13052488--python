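# chromophore: mu_a_melanin
# unit: mm^-1
# provenance: Jacques eumelanin power law 6.6e11*lambda^-3.33 cm^-1, converted to mm^-1
wavelength_nm,mu_a
400,142.786
410,131.515
420,121.373
430,112.226
440,103.955
450,96.4598
460,89.6521
470,83.4561
480,77.8056
490,72.6425
500,67.9163
510,63.5822
520,59.6009
530,55.9378
540,52.5621
550,49.4466
560,46.567
570,43.9016
580,41.4313
590,39.1387
600,37.0084
610,35.0264
620,33.1802
630,31.4586
640,29.8514
650,28.3493
660,26.944
670,25.628
680,24.3944
690,23.2368
700,22.1497
710,21.1278
720,20.1663
730,19.261
740,18.4078
750,17.6031
760,16.8436
770,16.1261
780,15.4479
790,14.8063
800,14.1989
810,13.6235
820,13.0781
830,12.5607
840,12.0696
850,11.6032
860,11.16
870,10.7385
880,10.3375
890,9.95578
900,9.59216
910,9.24562
920,8.91519
930,8.59995
940,8.29905
950,8.01169
960,7.73714
970,7.47471
980,7.22372
990,6.98359
1000,6.75373
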