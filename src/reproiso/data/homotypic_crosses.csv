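mother,father,replicates,females,males,males_dissected,males_motile
BAJ,BAJ,2,201,173,70,70
OAX,OAX,2,75,85,70,70
GUR,GUR,2,218,165,70,70
HTL,HTL,1,175,158,70,70
TEH,TEH,2,228,209,70,70
SON,SON,1,126,140,35,35
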