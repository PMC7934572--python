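accession	group	INS	DEL	DUP	INV	TRA	INVDUP
Peking	Primitive	7388	8975	370	97	1092	0
Moshidou Gong 503	Primitive	10959	12475	356	106	1106	0
C1329	World	3878	4348	156	47	698	1
PK 73-54	World	2645	2885	166	44	632	1
5002T	World	2151	2454	126	47	557	0
Williams 82	World	785	452	132	41	623	0
Houjaku Kuwazu	Japan	6254	6671	356	100	1011	0
Enrei	Japan	6432	7043	370	90	985	1
Fukuyutaka	Japan	6764	7458	348	92	1315	5
Misuzudaizu	Japan	2486	2821	143	46	648	0
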