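Gene Name,StarGazer Score,Odds-Ratio,OpenTargets Associations,Indicator Phe/GWAS,Druggability Score,Network Degree Score
HLA-DRB1,0.456,0.725,0.000,0.000,1.000,0.556
ESR1,0.433,0.655,0.009,0.000,0.500,1.000
GRIN2B,0.407,0.756,0.000,0.000,0.500,0.778
MEIS1,0.395,0.251,1.000,0.000,0.500,0.222
MAOA,0.344,0.888,0.000,0.000,0.500,0.333
DNM1,0.337,0.630,0.000,0.000,0.500,0.556
HLA-DQB1,0.320,0.653,0.000,0.000,0.500,0.444
BMP4,0.307,0.591,0.000,0.000,0.500,0.444
ATM,0.293,0.188,0.000,0.000,0.500,0.778
CMTM7,0.288,0.941,0.000,0.000,0.500,0.000
NKAPL,0.288,0.938,0.000,0.000,0.500,0.000
GRIA1,0.286,0.263,0.000,0.000,0.500,0.667
TOMM40,0.280,0.677,0.000,0.000,0.500,0.222
NR5A2,0.278,0.668,0.000,0.000,0.500,0.222
HDAC9,0.276,0.768,0.000,0.000,0.500,0.111
MS4A6A,0.271,0.631,0.000,0.000,0.500,0.222
DISC1,0.267,0.166,0.000,0.000,0.500,0.667
ST6GAL1,0.265,0.716,0.000,0.000,0.500,0.111
SLC22A3,0.264,0.600,0.000,0.000,0.500,0.222
EFNA5,0.264,0.600,0.000,0.000,0.500,0.222
NRGN,0.263,0.706,0.000,0.000,0.500,0.111
DRD2,0.263,0.000,0.150,0.000,0.500,0.667
RNASET2,0.263,0.591,0.000,0.000,0.500,0.222
FGFR2,0.263,0.257,0.000,0.000,0.500,0.556
UBE2L3,0.262,0.701,0.000,0.000,0.500,0.111
YDJC,0.260,0.690,0.000,0.000,0.500,0.111
CDC42BPB,0.260,0.690,0.000,0.000,0.500,0.111
LAMP3,0.258,0.791,0.000,0.000,0.500,0.000
ARG1,0.254,0.660,0.000,0.000,0.500,0.111
CCND3,0.251,0.643,0.000,0.000,0.500,0.111
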