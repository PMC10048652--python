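id,count,mean,sd,q1,q2,q3,cv,skewness,distribution
AID1,312212,147.94,60.27,101,139,185,40.74,0.37,Symmetrical
AID2,357587,144.51,47.51,110,135,171,32.88,0.93,Moderately Skewed
AID3,486197,133.09,50.68,96,123,160,38.08,1.08,Highly Skewed
AID4,282441,140.11,48.22,102,131,169,34.41,0.89,Moderately Skewed
AID5,242279,145.53,56,106,135,174,38.48,-0.12,Symmetrical
AID6,276622,140.05,58.85,99,126,167,42.02,0.89,Moderately Skewed
AID7,280822,127.89,43.35,97,120,151,33.9,1.04,Highly Skewed
AID8,206778,158.42,57.6,115,153,195,36.36,0.47,Symmetrical
AID9,201712,116.22,51.57,82,104,137,44.37,1.46,Highly Skewed
AID10,168848,147.35,55.88,107,135,177,37.92,1.08,Highly Skewed
AID11,163267,117.18,30.68,95,112,134,26.18,0.30,Symmetrical
AID12,145692,147.67,53.23,108,138,178,36.04,0.90,Moderately Skewed
AID13,122557,148.45,55.32,107,138,178,37.27,0.99,Moderately Skewed
AID14,102673,152.71,56.36,112,138,184,36.91,0.73,Moderately Skewed
AID15,104669,138.08,40.84,109,130,160,29.58,1.03,Highly Skewed
AID16,96270,143.14,59.29,101,131,175,41.42,0.98,Moderately Skewed
AID17,77946,134.24,46.37,100,126,162,34.54,0.13,Symmetrical
AID18,78798,98.42,33.3,76,91,114,33.84,1.43,Highly Skewed
AID19,27786,132.75,47.66,97,126,160,35.9,0.45,Symmetrical
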