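trait,model,aic,sigma2_a,sigma2_a_se,sigma2_d,sigma2_d_se,sigma2_aa,sigma2_aa_se,sigma2_ad,sigma2_ad_se,sigma2_dd,sigma2_dd_se,sigma2_e,sigma2_e_se,h2,h2_se,H2,H2_se,boundary
Ht1,PBLUP-A,5788.85,309.09,118.88,,,,,,,,,1469.49,114.45,0.17,0.06,,,
Ht1,PBLUP-AD,5786.88,269.57,122.53,501.60,283.39,,,,,,,1009.78,263.65,0.15,0.07,0.43,0.15,
Ht1,GBLUP-A,5793.20,328.42,120.30,,,,,,,,,1458.70,117.30,0.18,0.06,,,
Ht1,GBLUP-AD,5795.20,328.42,120.39,0.00,0.00,,,,,,,1458.70,117.30,0.18,0.06,0.18,0.06,d
Ht1,GBLUP-ADE,5801.07,299.03,142.39,0.00,0.00,138.34,380.26,0.00,0.00,0.00,0.00,1359.88,294.99,0.17,0.08,0.24,0.18,d;ad;dd
Ht2,PBLUP-A,6875.41,3828.13,1090.64,,,,,,,,,5818.22,726.37,0.39,0.09,,,
Ht2,PBLUP-AD,6876.84,3719.17,1093.87,847.19,1193.23,,,,,,,5068.48,1254.57,0.39,0.10,0.47,0.14,
Ht2,GBLUP-A,6890.86,2999.85,733.46,,,,,,,,,6443.27,584.16,0.32,0.07,,,
Ht2,GBLUP-AD,6892.76,2963.10,744.24,135.05,557.15,,,,,,,6343.47,712.08,0.31,0.07,0.33,0.08,
Ht2,GBLUP-ADE,6895.17,2166.02,819.39,0.56,536.44,3573.72,2090.50,0.01,0.00,0.01,0.00,3936.31,1502.41,0.22,0.08,0.59,0.16,ad;dd
DBH1,PBLUP-A,4998.46,148.85,49.45,,,,,,,,,456.93,40.62,0.25,0.07,,,
DBH1,PBLUP-AD,5000.46,148.85,49.45,0.00,0.00,,,,,,,456.93,40.62,0.25,0.07,0.25,0.07,d
DBH1,GBLUP-A,5007.54,132.64,40.75,,,,,,,,,471.71,38.19,0.22,0.06,,,
DBH1,GBLUP-AD,5009.55,132.64,40.75,0.00,0.00,,,,,,,471.71,38.19,0.22,0.06,0.22,0.06,d
DBH1,GBLUP-ADE,5015.53,129.79,48.38,0.00,0.00,13.76,125.13,0.00,0.00,0.00,0.00,461.83,99.53,0.21,0.08,0.24,0.18,d;ad;dd
DBH2,PBLUP-A,5216.79,161.69,57.95,,,,,,,,,625.69,51.62,0.21,0.07,,,
DBH2,PBLUP-AD,5217.50,152.87,59.02,115.72,111.27,,,,,,,519.30,109.33,0.19,0.07,0.34,0.14,
DBH2,GBLUP-A,5219.67,158.20,40.75,,,,,,,,,627.20,49.879,0.20,0.06,,,
DBH2,GBLUP-AD,5221.43,151.11,52.86,28.06,55.45,,,,,,,606.24,63.89,0.19,0.06,0.23,0.08,
DBH2,GBLUP-ADE,5225.99,107.21,61.39,7.22,56.47,239.73,193.79,0.00,0.00,0.00,0.00,449.86,138.42,0.13,0.08,0.44,0.18,ad;dd
MFA,PBLUP-A,2541.56,4.88,1.51,,,,,,,,,11.44,1.14,0.30,0.08,,,
MFA,PBLUP-AD,2541.56,4.88,1.51,0.00,0.00,,,,,,,11.44,1.14,0.30,0.08,0.30,0.08,d
MFA,GBLUP-A,2547.74,5.47,1.39,,,,,,,,,11.06,1.07,0.33,0.07,,,
MFA,GBLUP-AD,2549.74,5.47,1.39,0.00,0.00,,,,,,,11.06,1.07,0.33,0.07,0.33,0.07,d
MFA,GBLUP-ADE,2555.74,5.47,1.39,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,11.06,1.07,0.33,0.07,0.33,0.07,d;aa;ad;dd
MOEs,PBLUP-A,1377.57,1.31,0.37,,,,,,,,,1.81,0.24,0.42,0.10,,,
MOEs,PBLUP-AD,1379.57,1.31,0.37,0.00,0.00,,,,,,,1.81,0.24,0.42,0.10,0.42,0.10,d
MOEs,GBLUP-A,1383.02,1.34,0.28,,,,,,,,,1.78,0.19,0.43,0.07,,,
MOEs,GBLUP-AD,1385.02,1.34,0.28,0.00,0.00,,,,,,,1.78,0.19,0.43,0.07,0.43,0.07,d
MOEs,GBLUP-ADE,1391.02,1.34,0.28,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,1.78,0.19,0.43,0.07,0.43,0.07,d;aa;ad;dd
DEN,PBLUP-A,5233.81,407.20,110.34,,,,,,,,,497.16,70.32,0.45,0.10,,,
DEN,GBLUP-A,5232.72,376.82,75.66,,,,,,,,,506.02,52.22,0.43,0.07,,,
DEN,GBLUP-AD,5234.72,376.81,75.66,0.00,0.00,,,,,,,506.03,52.22,0.43,0.07,0.43,0.07,d
DEN,GBLUP-ADE,5239.82,341.84,83.2,0.00,0.00,176.33,183.68,0.00,0.00,0.00,0.00,378.78,138.75,0.38,0.08,0.58,0.17,d;ad;dd
MOEd,PBLUP-A,932.29,0.81,0.22,,,,,,,,,0.86,0.13,0.48,0.10,,,
MOEd,PBLUP-AD,934.29,0.81,0.21,0.00,0.00,,,,,,,0.86,0.13,0.48,0.10,0.48,0.10,d
MOEd,GBLUP-A,946.17,0.68,0.14,,,,,,,,,0.96,0.10,0.42,0.07,,,
MOEd,GBLUP-AD,948.17,0.68,0.14,0.00,0.00,,,,,,,0.96,0.10,0.42,0.07,0.42,0.07,d
MOEd,GBLUP-ADE,951.17,0.54,0.15,0.00,0.00,0.58,0.35,0.00,0.00,0.00,0.00,0.56,0.25,0.32,0.08,0.67,0.16,d;ad;dd
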