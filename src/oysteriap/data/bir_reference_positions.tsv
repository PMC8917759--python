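position	role	consensus_residue
27	conserved	L
30	conserved	P
34	conserved,key	G
38	conserved	W
45	conserved	F
50	conserved	L
57	conserved,key	C
60	conserved,key	C
63	conserved	F
70	conserved	G
76	conserved,key	E
77	conserved,key	H
80	conserved,key	W
81	key	S
82	key	K
84	conserved,key	C
88	conserved	L
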