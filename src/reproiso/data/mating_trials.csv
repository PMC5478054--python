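strain_a,strain_b,n11,n12,n21,n22,n_reported
BAJ,GUR,26,20,13,22,81
BAJ,OAX,30,15,9,27,81
BAJ,HTL,25,11,5,22,63
BAJ,TEH,22,15,13,27,77
BAJ,SON,23,13,10,27,73
GUR,OAX,24,24,17,16,81
GUR,TEH,13,24,17,18,72
GUR,HTL,10,21,19,13,63
GUR,SON,15,18,19,15,67
OAX,TEH,12,23,20,17,72
OAX,HTL,11,19,19,15,64
OAX,SON,9,17,19,12,66
TEH,HTL,16,16,21,11,64
TEH,SON,13,24,27,18,83
HTL,SON,14,14,18,13,59
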