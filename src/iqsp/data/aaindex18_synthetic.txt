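H QIAN880137
D Weights for coil at the window position of 4 (Qian-Sejnowski, 1988)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.104   0.632  -1.271  -1.065   1.776   0.628  -1.251   0.166   0.169   1.894
  -0.157   0.276  -0.039  -0.687   0.106  -0.887  -0.898  -0.482   0.732  -1.210
//
H AURR980102
D Normalized positional residue frequency at helix termini N' (Aurora-Rose, 1998)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.416   1.097   1.121   0.534   0.218  -0.028  -1.257   0.732   0.094  -1.436
   0.077  -0.531  -0.225   1.409  -0.378   0.796   0.794  -0.457   0.092  -1.657
//
H ROBB760113
D Information measure for loop (Robson-Suzuki, 1976)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.146  -0.433  -2.623  -0.845   2.139  -0.297   0.327   0.964   0.304  -1.862
  -0.183   0.087   0.353  -0.201  -0.062  -0.095   0.911  -0.734   1.160  -0.664
//
H PRAM820101
D Intercept in regression analysis (Prabhakaran-Ponnuswamy, 1982)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.969  -2.295  -0.063  -0.136   1.350   0.240  -0.519   1.014  -0.934  -0.867
   0.343   1.436   0.472  -0.021  -3.311  -1.889  -0.840  -0.384   0.194   2.233
//
H GRAR740101
D Composition (Grantham, 1974)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.574   0.402   0.394  -0.413  -0.051  -1.335   1.214  -0.642   0.801  -0.602
   0.342   0.587   0.006  -0.505   0.247   0.058  -1.788  -1.546   1.847  -1.844
//
H PALJ810111
D Normalized frequency of beta-sheet in alpha + beta class (Palau et al., 1981)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.182   0.474   0.918   0.117  -0.263  -0.094   1.553   1.283   0.537   0.979
   0.351   2.208  -1.869   0.462  -0.563  -1.300  -1.995   0.492   0.273  -0.940
//
H PONP800102
D Average gain in surrounding hydrophobicity (Ponnuswamy et al., 1980)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.298   0.945  -1.305  -1.525   0.384   0.634  -0.639  -1.742   0.101   0.505
  -1.205   0.164  -0.635  -0.799  -0.457  -0.507  -0.719  -0.152   2.006   1.111
//
H MUNV940103
D Free energy in beta-strand conformation (Munoz-Serrano, 1994)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.019   0.242  -0.190   0.374   0.497   0.457   0.587  -1.007   0.842  -0.167
  -1.003   1.571  -1.426   1.174  -0.019   1.380  -0.219   0.595  -0.075   1.135
//
H DAYM780101
D Amino acid composition (Dayhoff et al., 1978a)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.399  -0.120   0.517  -0.162   0.287  -0.617   0.951  -0.965  -1.105   0.599
   1.736   0.204   1.454  -0.064  -0.556   1.504  -1.440  -1.637   0.595   0.945
//
H MANP780101
D Average surrounding hydrophobicity (Manavalan-Ponnuswamy, 1978)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.516   0.918  -1.093  -0.146  -0.149   0.979   0.841  -0.947   2.679  -0.064
  -0.964   0.546   0.966   0.879   0.567  -0.223   1.260   0.282  -0.408  -1.494
//
H KUMS000103
D Distribution of amino acid residues in the alpha-helices in thermophilic proteins (Kumar et al., 2000)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.103  -0.039   0.845   0.021   1.379  -0.021   1.068  -0.713  -0.613   1.224
  -0.447  -0.699   1.143   1.160  -1.939   0.194   1.517   0.327   1.204  -0.723
//
H ROBB760104
D Information measure for C-terminal helix (Robson-Suzuki, 1976)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.234   1.426   0.304  -0.011   0.474  -0.308   0.282  -0.531   0.564  -0.536
   1.253  -0.531   1.405  -0.640  -0.746   0.822  -0.784  -1.223   0.382  -0.038
//
H ISOY800107
D Normalized relative frequency of double bend (Isogai et al., 1980)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.993  -0.221   0.986  -0.880  -1.062  -0.855  -0.661   1.152  -0.464   2.111
   1.613   0.344   1.352  -1.720   1.260  -1.608  -1.386   1.169   0.415  -1.149
//
H GEIM800101
D Alpha-helix indices (Geisow-Roberts, 1980)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -1.507  -1.447   0.199   0.733  -0.678  -0.442  -0.077  -0.966   0.379   0.012
   1.010   2.651  -0.830  -1.074  -2.736   0.238  -0.833   0.969  -0.563   0.036
//
H PRAM900102
D Relative frequency in alpha-helix (Prabhakaran, 1990)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.750  -0.493  -0.375  -0.368  -0.211   0.238   1.968  -1.654   1.314   0.017
  -1.490  -0.208   0.390   0.505  -1.023  -0.163   0.019  -0.846   1.499  -0.468
//
H NADH010104
D Hydropathy scale based on self-information values in the two-state model (20% accessibility) (Naderi-Manesh et al., 2001)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.201  -0.495   1.029   0.343  -2.158   1.039   1.700  -0.946  -0.870  -0.047
   1.564  -0.845   0.831   0.798  -0.580  -1.553  -0.704  -2.330  -0.894   2.232
//
H FUKS010106
D Interior composition of amino acids in intracellular proteins of mesophiles (percent) (Fukuchi-Nishikawa, 2001)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.477   0.559   1.015   0.138   0.409  -0.384  -0.233   0.622  -0.920   1.154
  -1.423  -0.515   1.154   0.370  -1.288   1.617  -0.406   0.450   0.159  -0.098
//
H WIMW960101
D Free energies of transfer of AcWl-X-LL peptides from bilayer interface to water (Wimley-White, 1996)
R synthetic stand-in values, not the published scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.340   1.349  -0.494  -0.341   2.058  -0.512   0.852   0.932   1.223   0.438
   0.334   1.103   0.677  -1.206  -0.134  -1.785  -0.111  -0.634   0.422   2.167
//
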