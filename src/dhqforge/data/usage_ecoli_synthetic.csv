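codon,amino_acid,fraction
GCA,A,0.097745
GCC,A,0.23033
GCG,A,0.118362
GCT,A,0.553564
TGC,C,0.729702
TGT,C,0.270298
GAC,D,0.194305
GAT,D,0.805695
GAA,E,0.600037
GAG,E,0.399963
TTC,F,0.393064
TTT,F,0.606936
GGA,G,0.075248
GGC,G,0.304817
GGG,G,0.562069
GGT,G,0.057866
CAC,H,0.37267
CAT,H,0.62733
ATA,I,0.424047
ATC,I,0.477089
ATT,I,0.098864
AAA,K,0.856149
AAG,K,0.143851
CTA,L,0.04009
CTC,L,0.23372
CTG,L,0.327877
CTT,L,0.231482
TTA,L,0.120285
TTG,L,0.046547
ATG,M,1.0
AAC,N,0.147667
AAT,N,0.852333
CCA,P,0.318525
CCC,P,0.170962
CCG,P,0.166022
CCT,P,0.344491
CAA,Q,0.434826
CAG,Q,0.565174
AGA,R,0.194099
AGG,R,0.162317
CGA,R,0.140001
CGC,R,0.08829
CGG,R,0.017872
CGT,R,0.39742
AGC,S,0.088156
AGT,S,0.288543
TCA,S,0.065143
TCC,S,0.169241
TCG,S,0.319966
TCT,S,0.068953
ACA,T,0.167132
ACC,T,0.433262
ACG,T,0.198742
ACT,T,0.200864
GTA,V,0.351707
GTC,V,0.093141
GTG,V,0.29462
GTT,V,0.260532
TGG,W,1.0
TAC,Y,0.1054
TAT,Y,0.8946
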