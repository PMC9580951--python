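BRDT,BRD2,BRD4
BRD1,PBRM1,TRIM33
BPTF,BRD2,BRD3,BRD4
ZMYND11,BRD4,SMARCA2
ZMYND11,BRD4,BRPF3
BAZ2A,BAZ1B,BRD2
BAZ2A,BAZ1B,TRIM33
KMT2A,SMARCA2,BRD4,TAF1
KMT2A,SMARCA2,BRD4,CBP
BRPF1,BRPF3,TAF1
BRPF1,BRD2,TAF1
BRPF1,BRD2,ZMYND8
BRPF1,BRD2,TRIM24
KAT2B,CBP,P300,SMARCA2
KAT2B,CBP,P300,KAT2A
KAT2A,CBP,BRD4,P300
P300,SMARCA2,BRD7
P300,SMARCA2,BRD4,CBP
BAZ1A,BRD4,BRD3,SMARCA2
BAZ1A,BRD4,BRD3,BAZ1B
BRD8,TAF1,BRPF3,SP110,BRD4
ZMYND8,SMARCA4,BRD4,TRIM28
ZMYND8,SMARCA4,BRD4,BRD3,BRD2
CBP,TRIM28,TRIM24
CBP,TRIM28,BRD4,SMARCA4,SMARCA2
PHIP,BRD2,BRD3,BRD4,TAF1
PHIP,BRD2,BRD3,BRD4,PBRM1,SMARCA4
TRIM24,BRD2,BRD7
TRIM24,TRIM28,BRD7
TRIM24,TRIM28,TRIM33
TAF1,SMARCA2,BRD3,BRD4,BRD2
BRD9,SMARCA2,BRD3,BRD4,BRD2,SMARCA4
PBRM1,SMARCA2,SMARCA4,TRIM33,BRD4
PBRM1,SMARCA2,SMARCA4,BRD3,BRD2,BRD7
PBRM1,SMARCA2,SMARCA4,BRD3,BRD2,BRD4
SMARCA2,SMARCA4,TRIM28,BRD7
SMARCA2,SMARCA4,TRIM28,TRIM33,BRD4
SMARCA4,BAZ1B,BRD4,TRIM28,TRIM33
SMARCA4,BAZ1B,BRD4,BRD3,BRD2
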