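mother,father,chi2,sig_chi2
BAJ,BAJ,2.1,0
OAX,OAX,0.62,0
GUR,GUR,6.08,0
HTL,HTL,0.86,0
TEH,TEH,0.82,0
SON,SON,0.737,0
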