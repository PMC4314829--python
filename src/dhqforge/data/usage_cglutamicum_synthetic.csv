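codon,amino_acid,fraction
GCA,A,0.505314
GCC,A,0.102012
GCG,A,0.095369
GCT,A,0.297305
TGC,C,0.928077
TGT,C,0.071923
GAC,D,0.578141
GAT,D,0.421859
GAA,E,0.241007
GAG,E,0.758993
TTC,F,0.562304
TTT,F,0.437696
GGA,G,0.170329
GGC,G,0.27942
GGG,G,0.383572
GGT,G,0.166679
CAC,H,0.976251
CAT,H,0.023749
ATA,I,0.054313
ATC,I,0.867861
ATT,I,0.077826
AAA,K,0.621824
AAG,K,0.378176
CTA,L,0.017915
CTC,L,0.227771
CTG,L,0.238456
CTT,L,0.059192
TTA,L,0.225831
TTG,L,0.230835
ATG,M,1.0
AAC,N,0.102981
AAT,N,0.897019
CCA,P,0.144957
CCC,P,0.459053
CCG,P,0.034406
CCT,P,0.361584
CAA,Q,0.497518
CAG,Q,0.502482
AGA,R,0.054064
AGG,R,0.49242
CGA,R,0.045145
CGC,R,0.055199
CGG,R,0.201602
CGT,R,0.151571
AGC,S,0.376225
AGT,S,0.057807
TCA,S,0.021734
TCC,S,0.321059
TCG,S,0.033675
TCT,S,0.1895
ACA,T,0.252586
ACC,T,0.308807
ACG,T,0.2733
ACT,T,0.165306
GTA,V,0.111459
GTC,V,0.24573
GTG,V,0.276402
GTT,V,0.366409
TGG,W,1.0
TAC,Y,0.744074
TAT,Y,0.255926
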