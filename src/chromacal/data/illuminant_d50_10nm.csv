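wavelength_nm,power
380,24.49
390,29.87
400,49.31
410,56.51
420,60.03
430,57.82
440,74.82
450,87.25
460,90.61
470,91.37
480,95.11
490,91.96
500,95.72
510,96.61
520,97.13
530,102.10
540,100.75
550,102.32
560,100.00
570,97.74
580,98.92
590,93.50
600,97.69
610,99.27
620,99.04
630,95.72
640,98.86
650,95.67
660,98.19
670,103.00
680,99.13
690,87.38
700,91.60
710,92.89
720,76.85
730,86.51
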