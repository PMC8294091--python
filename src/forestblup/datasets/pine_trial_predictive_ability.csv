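trait,method,effects,r1_additive,r1_total,r2_additive,r2_total
Ht1,GBLUP,A,0.20,,0.46,
Ht1,GBLUP,AD,0.20,0.19,0.46,0.44
Ht1,GBLUP,ADE,0.20,0.19,0.47,0.38
Ht1,PBLUP,A,0.22,,0.53,
Ht1,PBLUP,AD,0.22,0.22,0.57,0.54
Ht2,GBLUP,A,0.33,,0.59,
Ht2,GBLUP,AD,0.33,0.33,0.60,0.58
Ht2,GBLUP,ADE,0.33,0.34,0.71,0.44
Ht2,PBLUP,A,0.38,,0.61,
Ht2,PBLUP,AD,0.38,0.37,0.61,0.55
DBH1,GBLUP,A,0.26,,0.54,
DBH1,GBLUP,AD,0.26,0.25,0.54,0.54
DBH1,GBLUP,ADE,0.26,0.25,0.56,0.52
DBH1,PBLUP,A,0.30,,0.58,
DBH1,PBLUP,AD,0.30,0.29,0.59,0.58
DBH2,GBLUP,A,0.23,,0.50,
DBH2,GBLUP,AD,0.23,0.22,0.52,0.46
DBH2,GBLUP,ADE,0.23,0.23,0.63,0.35
DBH2,PBLUP,A,0.25,,0.55,
DBH2,PBLUP,AD,0.25,0.24,0.58,0.42
MFA,GBLUP,A,0.32,,0.56,
MFA,GBLUP,AD,0.32,0.32,0.56,0.56
MFA,GBLUP,ADE,0.32,0.32,0.56,0.56
MFA,PBLUP,A,0.33,,0.60,
MFA,PBLUP,AD,0.33,0.33,0.60,0.60
MOEs,GBLUP,A,0.40,,0.62,
MOEs,GBLUP,AD,0.40,0.40,0.62,0.62
MOEs,GBLUP,ADE,0.40,0.40,0.62,0.62
MOEs,PBLUP,A,0.41,,0.63,
MOEs,PBLUP,AD,0.41,0.41,0.63,0.63
DEN,GBLUP,A,0.40,,0.62,
DEN,GBLUP,AD,0.40,0.40,0.62,0.62
DEN,GBLUP,ADE,0.40,0.41,0.66,0.54
DEN,PBLUP,A,0.41,,0.61,
DEN,PBLUP,AD,0.41,0.41,0.61,0.61
MOEd,GBLUP,A,0.42,,0.65,
MOEd,GBLUP,AD,0.42,0.42,0.65,0.65
MOEd,GBLUP,ADE,0.42,0.42,0.74,0.52
MOEd,PBLUP,A,0.43,,0.63,
MOEd,PBLUP,AD,0.43,0.43,0.63,0.63
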