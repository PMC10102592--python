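GENE	KINASE	KIN_ORGANISM	SUB_GENE	SUB_MOD_RSD	SUB_ORGANISM
AKT1	Akt1	human	GSK3B	S9	human
AKT1	Akt1	human	AKT1S1	T246	human
AKT1	Akt1	human	FOXO3	S253	human
AKT1	Akt1	human	BAD	S99	human
AKT1	Akt1	human	TSC2	S939	human
AKT1	Akt1	human	MDM2	S166	human
MAPK3	ERK1	human	RPS6KA1	T359	human
MAPK3	ERK1	human	ELK1	S383	human
MAPK3	ERK1	human	STMN1	S25	human
MAPK3	ERK1	human	JUN	S73	human
MAPK8	JNK1	human	JUN	S63	human
MAPK8	JNK1	human	ATF2	T71	human
MAPK8	JNK1	human	DCX	T321	human
CDK2	CDK2	human	RB1	S807	human
CDK2	CDK2	human	NPM1	T199	human
CDK2	CDK2	human	CDC6	S54	human
CDK2	CDK2	human	CDT1	T29	human
AURKB	AurB	human	VIM	S72	human
AURKB	AurB	human	DES	T17	human
AURKB	AurB	human	KIF23	S911	human
CSNK1A1	CK1A	human	CTNNB1	S45	human
CSNK1A1	CK1A	human	PER2	S662	human
CSNK1A1	CK1A	human	NFATC3	S265	human
CSNK1A1	CK1A	human	YAP1	S61	human
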