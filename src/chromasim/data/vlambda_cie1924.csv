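wavelength_nm,weight
380,0.00004
390,0.00012
400,0.0004
410,0.0012
420,0.0040
430,0.0116
440,0.023
450,0.038
460,0.060
470,0.091
480,0.139
490,0.208
500,0.323
510,0.503
520,0.710
530,0.862
540,0.954
550,0.995
560,0.995
570,0.952
580,0.870
590,0.757
600,0.631
610,0.503
620,0.381
630,0.265
640,0.175
650,0.107
660,0.061
670,0.032
680,0.017
690,0.0082
700,0.0041
710,0.0021
720,0.00105
730,0.00052
740,0.00025
750,0.00012
760,0.00006
770,0.00003
780,0.000015
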