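ASH1L
ATAD2
ATAD2B
BAZ1A
BAZ1B
BAZ2A
BAZ2B
BPTF
BRD1
BRD2
BRD3
BRD4
BRD7
BRD8
BRD9
BRDT
BRPF1
BRPF3
BRWD1
BRWD3
CBP
CECR2
KAT2A
KAT2B
KMT2A
P300
PBRM1
PHIP
SMARCA2
SMARCA4
SP100
SP110
SP140
SP140L
TAF1
TAF1L
TRIM24
TRIM28
TRIM33
TRIM66
ZMYND8
ZMYND11
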