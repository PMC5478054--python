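strain_a,strain_b,chi2,sig_chi2,I,se_I,sig_I,I1,se_I1,sig_I1,I2,se_I2,sig_I2
BAJ,GUR,4.38,0,0.19,0.11,0,0.26,0.11,1,0.13,0.11,0
BAJ,OAX,14.55,1,0.41,0.10,1,0.33,0.10,1,0.50,0.10,1
BAJ,HTL,16.68,1,0.49,0.11,1,0.39,0.12,1,0.63,0.10,1
BAJ,TEH,6.48,0,0.27,0.11,1,0.19,0.11,0,0.35,0.11,1
BAJ,SON,10.67,0,0.37,0.11,1,0.28,0.11,1,0.46,0.10,1
GUR,OAX,2.8,0,-0.01,0.11,0,0.00,0.11,0,-0.03,0.11,0
GUR,TEH,3.44,0,-0.14,0.12,0,-0.30,0.11,1,0.03,0.12,0
GUR,HTL,5.0,0,-0.27,0.12,1,-0.35,0.12,1,-0.19,0.12,0
GUR,SON,0.76,0,-0.10,0.12,0,-0.09,0.12,0,-0.12,0.12,0
OAX,TEH,2.66,0,-0.19,0.12,0,-0.31,0.11,1,-0.08,0.12,0
OAX,HTL,2.75,0,-0.19,0.12,0,-0.27,0.12,1,-0.12,0.12,0
OAX,SON,4.18,0,-0.24,0.12,1,-0.29,0.12,1,-0.20,0.12,0
TEH,HTL,3.12,0,-0.16,0.12,0,0.00,0.13,0,-0.31,0.12,1
TEH,SON,5.65,0,-0.24,0.11,1,-0.30,0.11,1,-0.20,0.11,0
HTL,SON,1.0,0,-0.08,0.13,0,0.00,0.13,0,-0.16,0.13,0
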