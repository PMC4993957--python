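Glu,Mal,Mann,CP,Yeast,CS,SC,FS,VB1,TF
15.04,15.2,29.97,5.27,5.09,0.18,0.22,9.8,1,2220
15.13,15.27,29.85,5,5.16,0.2,0.23,9.82,1.08,2220
15.04,15.63,29.81,5.16,5.11,0.19,0.55,9.96,1.01,2220
15.03,15.64,29.98,6.35,5.39,0.16,0.4,9.81,1.11,2200
15.09,15.1,29.82,5.1,5.24,0.2,0.23,9.99,1.08,2230
15.13,15.04,29.6,5.1,5.15,0.19,0.22,9.74,1,2210
15.01,15.13,29.81,5.14,5.06,0.16,0.22,9.88,1.01,2230
15.01,15.2,29.46,5.06,5.09,0.2,0.27,9.94,1.1,2220
15.02,15.39,29.99,5.02,5.1,0.2,0.29,9.99,1,2230
15.52,15.04,29.98,5.21,5.09,0.18,0.32,9.98,1,2220
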