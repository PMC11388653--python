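dr,fsel,classifier,acc,f1,mcc,er,ji,csi,gmean,kappa
HT,none,BLDC,82.32,88.32,0.5757,17.67,79.08,78.24,69.23,0.5326
HT,none,NBC,58.565,69.63,0.1651,41.43,53.41,45.99,45.94,0.1302
HT,none,RFC,58.563,69.87,0.1459,41.437,53.703,45.87,45.12,0.1167
HT,none,DTC,79.005,86.89,0.3495,20.99,76.83,74,61.087,0.3443
HT,none,SVM_linear,75.138,83.271,0.4135,24.862,71.337,68.784,60.359,0.3729
HT,none,SVM_poly,64.641,74.19,0.3173,35.36,58.974,55.21,53.17,0.2521
HT,none,SVM_rbf,67.403,76.49,0.3631,32.597,61.93,59.049,55.579,0.2942
DFA,none,BLDC,55.24,66.93,0.09604,44.76,50.31,40.98,42.51,0.0747
DFA,none,NBC,87.29,91.982,0.6312,12.71,85.16,84.35,75.45,0.6162
DFA,none,RFC,67.95,77.69,0.2955,32.05,63.52,59.15,53.33,0.2533
DFA,none,DTC,60.77,70.53,0.2811,39.23,54.48,50.07,50.93,0.2126
DFA,none,SVM_linear,85.08,91.02,0.4677,14.92,83.53,82.06,71.71,0.4678
DFA,none,SVM_poly,61.32,73.076,0.1153,38.68,57.57,49.69,44.11,0.0988
DFA,none,SVM_rbf,60.22,70.24,0.2568,39.78,54.14,49.05,49.92,0.1956
LSLR,none,BLDC,73.48,81.53,0.4457,26.52,68.83,67.03,60.53,0.3821
LSLR,none,NBC,58.56,68.08,0.2808,41.44,51.61,47.45,50.48,0.2031
LSLR,none,RFC,56.35,68.27,0.0871,43.65,51.82,42.52,42.18,0.0696
LSLR,none,DTC,56.35,68.52,0.0678,43.65,52.12,42.48,41.26,0.0549
LSLR,none,SVM_linear,79.01,86.89,0.3495,20.99,76.82,74,61.08,0.3443
LSLR,none,SVM_poly,63.53,74.81,0.1564,36.47,59.75,52.83,46.43,0.1357
LSLR,none,SVM_rbf,76.79,84.67,0.4179,23.21,73.41,70.88,61.44,0.3866
HT,EHO,BLDC,69.06,78.62,0.3074,30.94,64.77,60.63,54.14,0.2666
HT,EHO,NBC,81.76,88.58,0.4448,18.24,79.5,77.42,66.21,0.4369
HT,EHO,RFC,69.06,77.95,0.381,30.94,63.87,61.19,56.69,0.3139
HT,EHO,DTC,81.76,88,0.5522,18.24,78.57,77.46,68.31,0.5134
HT,EHO,SVM_linear,56.35,66.94,0.1831,43.64,50.31,43.22,46.36,0.1364
HT,EHO,SVM_poly,57.45,68.04,0.1931,42.56,51.57,44.77,46.93,0.1461
HT,EHO,SVM_rbf,59.66,69.19,0.2905,40.34,52.9,48.91,51.05,0.2133
DFA,EHO,BLDC,75.13,83.87,0.3271,24.87,72.22,68.69,57.56,0.3096
DFA,EHO,NBC,60.22,69.49,0.3151,39.78,53.24,50.01,52.05,0.2296
DFA,EHO,RFC,86.18,91.52,0.5449,13.82,84.37,83.12,73.69,0.5426
DFA,EHO,DTC,91.71,94.88,0.7378,8.29,90.25,89.86,83.11,0.7321
DFA,EHO,SVM_linear,92.26,95.36,0.7209,7.74,91.139,90.73,86.68,0.7203
DFA,EHO,SVM_poly,67.4,77.73,0.2344,32.6,63.58,58.23,50.77,0.2069
DFA,EHO,SVM_rbf,85.08,90.18,0.6474,14.92,82.11,81.86,72.89,0.6018
LSLR,EHO,BLDC,62.43,71.91,0.3155,37.57,56.12,52.56,52.56,0.2403
LSLR,EHO,NBC,65.74,75.2,0.3281,34.26,60.25,56.66,53.86,0.2641
LSLR,EHO,RFC,87.84,92.56,0.5943,12.16,86.16,85.16,76.79,0.5926
LSLR,EHO,DTC,85.63,91.15,0.5332,14.37,83.75,82.38,72.67,0.531
LSLR,EHO,SVM_linear,88.95,93.19,0.6422,11.05,87.26,86.47,78.55,0.6385
LSLR,EHO,SVM_poly,62.43,72.13,0.2964,37.57,56.41,52.28,51.86,0.2291
LSLR,EHO,SVM_rbf,90.61,94.11,0.7228,9.39,88.88,88.51,80.76,0.7099
HT,CS,BLDC,80.66,87.81,0.4261,19.34,78.26,75.97,64.65,0.4159
HT,CS,NBC,65.74,76.33,0.2168,34.26,61.72,55.95,49.58,0.1881
HT,CS,RFC,67.95,77.34,0.3321,32.05,63.05,59.39,54.66,0.2779
HT,CS,DTC,83.97,89.75,0.5574,16.03,81.41,80.15,70.52,0.5364
HT,CS,SVM_linear,73.48,82.35,0.3408,26.52,70,66.46,57.16,0.3122
HT,CS,SVM_poly,67.95,77.86,0.2772,32.05,63.75,59.07,52.64,0.2404
HT,CS,SVM_rbf,70.71,79.53,0.3795,29.29,66.02,63.16,57.28,0.3234
DFA,CS,BLDC,69.06,79.25,0.2343,30.94,65.64,60.5,51.29,0.2124
DFA,CS,NBC,70.71,79.53,0.3795,29.29,66.02,63.16,57.28,0.3234
DFA,CS,RFC,69.06,79.1,0.2527,30.94,65.43,60.49,52.04,0.2267
DFA,CS,DTC,90.05,94.03,0.6409,9.95,88.75,88.08,82.24,0.6404
DFA,CS,SVM_linear,85.63,91.15,0.5332,14.36,83.75,82.38,72.67,0.531
DFA,CS,SVM_poly,75.69,84.39,0.3171,24.31,73.006,69.48,57.54,0.3039
DFA,CS,SVM_rbf,91.71,94.88,0.7378,8.29,90.25,89.86,83.11,0.7321
LSLR,CS,BLDC,56.35,67.48,0.1445,43.65,50.93,42.83,44.76,0.1109
LSLR,CS,NBC,71.82,80.89,0.3385,28.18,67.92,64.31,56.33,0.3021
LSLR,CS,RFC,65.74,76.15,0.2354,34.26,61.49,56,50.355,0.2018
LSLR,CS,DTC,58.56,69.87,0.1459,41.44,53.71,45.88,45.12,0.1167
LSLR,CS,SVM_linear,58.56,69.38,0.18414,41.44,53.125,46.14,46.74,0.1432
LSLR,CS,SVM_poly,60.77,71.02,0.2428,39.23,55.06,49.57,49.48,0.1889
LSLR,CS,SVM_rbf,91.71,94.88,0.7378,8.29,90.25,89.86,83.11,0.73206
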