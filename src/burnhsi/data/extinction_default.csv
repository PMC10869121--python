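# Chromophore extinction table v1: oxy/deoxy-Hb after the Prahl compilation
# (tetramer molar extinction, L mol^-1 cm^-1, resampled to 10 nm); metHb after
# Zijlstra et al. (tetramer basis); melanin as interior-melanosome absorption
# power law 6.6e11 * lambda_nm^-3.33 cm^-1.
wavelength_nm,eps_hbo,eps_hbr,eps_methb,mu_mel
450,62816,62648,20000,964.60
460,44480,47540,24000,896.52
470,33209,39046,28800,834.56
480,26629,32851,33000,778.06
490,23684,27494,35600,726.43
500,20932,20862,36400,679.16
510,20035,25773,34800,635.82
520,24202,31590,31600,596.01
530,39956,39036,28400,559.38
540,53236,46592,26000,525.62
550,43016,53412,24200,494.47
560,32613,53788,22000,465.67
570,44496,49952,19400,439.02
580,50104,37020,17000,414.31
590,14648,28324,14000,391.39
600,3200,14677,12200,370.08
610,1506,9443,12400,350.26
620,942,6509,13800,331.80
630,610,5149,15600,314.59
640,442,4345,14200,298.51
650,368,3750,10600,283.49
660,319,3227,7200,269.44
670,294,2795,5000,256.28
680,277,2407,3600,243.94
690,276,2051,2800,232.37
700,290,1794,2200,221.50
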