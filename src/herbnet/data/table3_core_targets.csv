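name,Betweenness,Closeness,Degree,Eigenvector,LAC,Network
RXRA,2687.96,0.13922,25,0.12621,4.88,12.3559
MAPK14,1320.3,0.13782,26,0.17326,6.30769,11.1306
CDKN1A,233.359,0.13454,21,0.15742,9.52381,13.2798
AKT1,1869.26,0.14017,38,0.22659,7,19.8584
BCL2,107.624,0.13344,11,0.09191,5.63636,6.86429
IL1B,195.7,0.12934,11,0.04401,4.90909,7.05476
RXRB,250.921,0.13301,12,0.07465,4,5.89621
HSP90AA1,2771.82,0.14114,43,0.23762,6.93023,22.243
PRKCB,85.6513,0.13089,11,0.07095,3.09091,3.80556
RUNX2,348.262,0.13355,17,0.1293,5.05882,5.93452
ESR1,1692.79,0.14005,29,0.19676,7.31034,14.5341
CXCL8,104.972,0.12813,8,0.03548,4.5,5.2
STAT1,1018.84,0.13805,22,0.14938,5.45455,8.69562
MAPK1,1229.31,0.14089,36,0.23698,8.16667,19.4127
NCOA1,585.12,0.1329,17,0.07494,3.52941,6.92806
RELA,1631.23,0.13969,31,0.18097,6.96774,16.1015
PPARA,728.316,0.13689,15,0.11076,5.73333,6.98726
NCOA2,168.545,0.13078,12,0.05747,4,5.76299
ERBB2,152.56,0.13026,9,0.0467,2.88889,3.64286
MTOR,260.533,0.13388,11,0.07371,3.45455,4.01944
AR,256.025,0.13644,15,0.10626,3.46667,4.0092
CAV1,810.179,0.13576,17,0.08522,2.70588,4.175
EGFR,1451.62,0.13758,22,0.13507,5.72727,9.89161
NFKBIA,243.095,0.13599,15,0.11526,6.4,7.94185
NOS2,227.327,0.13498,12,0.0959,5.16667,5.91515
NR3C1,198.853,0.13701,16,0.13489,6.125,7.04221
CDK1,514.874,0.13476,18,0.11604,8.11111,11.7764
CCND1,308.934,0.13421,20,0.14082,7.9,11.2294
PPARG,267.442,0.13509,12,0.07464,2.83333,3.62045
CASP8,609.654,0.13377,15,0.08938,3.33333,5.52082
CASP3,710.58,0.13454,19,0.12226,5.78947,9.58247
VEGFA,493.724,0.13047,12,0.05159,2.83333,4.9013
PRKCA,711.546,0.13667,17,0.1049,4.35294,5.95765
FOS,1103.71,0.13816,24,0.15232,6.16667,10.0468
CCNA2,98.4386,0.12853,15,0.08513,7.73333,10.7219
EGF,364.006,0.13226,11,0.06158,3.63636,4.375
TP53,2872.22,0.14101,40,0.25484,8.5,21.4317
RB1,479.563,0.13712,23,0.17401,8.43478,12.4595
BIRC5,230.993,0.13037,12,0.07336,3.83333,5.2803
MAPK3,1344.82,0.1415,38,0.25227,8.89474,21.9116
MDM2,471.96,0.1341,17,0.12263,6.11765,7.78631
MYC,436.551,0.13851,23,0.19177,8.78261,11.7684
HIF1A,269.255,0.13793,17,0.15341,7.41176,8.39529
TNF,1023.1,0.1361,23,0.11493,5.73913,11.9109
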