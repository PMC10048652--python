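id,sd_roc,tbr,tir,tar,lbgi,hbgi,gmi,j_index
AID1,1.45,6.24,67.13,26.63,1.48,5.85,6.85,43.35
AID2,1.07,1.7,77.77,20.52,0.54,4.42,6.77,36.87
AID3,1.68,5.78,78.05,16.17,1.42,3.64,6.49,33.77
AID4,1.15,1.42,79.1,19.48,0.68,4.12,6.66,35.47
AID5,1.53,4.14,74.33,21.54,0.99,5.1,6.79,40.61
AID6,1.74,4.68,76.29,19.03,1.2,4.77,6.66,39.56
AID7,1.35,4.56,83.76,11.68,1.25,2.71,6.37,29.32
AID8,1.73,3.97,63.6,32.43,0.93,6.84,7.1,46.66
AID9,1.72,14.51,75.06,10.43,3.26,2.56,6.09,28.15
AID10,1.6,2.42,74.36,23.23,0.73,5.31,6.83,41.3
AID11,0.89,2.33,93.9,3.77,0.98,1.23,6.11,21.86
AID12,1.58,2.6,73.55,23.86,0.74,5.19,6.84,40.36
AID13,0.79,2.37,74,23.63,0.73,5.41,6.86,41.52
AID14,2.05,0.78,73.45,25.76,0.43,5.9,6.96,43.71
AID15,1.7,0.83,84.51,14.66,0.41,3.32,6.61,32.01
AID16,1.94,6.13,71.66,22.21,1.48,5.17,6.73,40.98
AID17,1.52,4.3,79.7,16,1.14,3.45,6.52,32.62
AID18,0.95,16.97,80.42,2.6,3.82,0.74,5.66,17.35
AID19,1.59,5.21,79.55,15.24,1.34,3.4,6.49,32.55
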