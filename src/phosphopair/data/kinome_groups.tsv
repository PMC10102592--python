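kinase	group
MAPK1	CMGC
MAPK3	CMGC
MAPK8	CMGC
MAPK9	CMGC
MAPK13	CMGC
MAPK14	CMGC
CDK1	CMGC
CDK2	CMGC
CDK4	CMGC
CDK6	CMGC
CDK7	CMGC
GSK3A	CMGC
GSK3B	CMGC
DYRK1A	CMGC
CLK1	CMGC
AKT1	AGC
AKT2	AGC
SGK1	AGC
LATS1	AGC
PRKCA	AGC
PRKCZ	AGC
KPCZ	AGC
STK38	AGC
RPS6KB1	AGC
KS6B1	AGC
AURKB	AGC
PDPK1	AGC
ROCK1	AGC
PRKACA	AGC
CAMK2A	CAMK
CAMK2B	CAMK
CHEK1	CAMK
CHEK2	CAMK
MAPKAPK2	CAMK
PRKAA1	CAMK
PRKAA2	CAMK
MARK2	CAMK
PIM1	CAMK
DCLK1	CAMK
CSNK1A1	CK1
CSNK1D	CK1
CSNK1E	CK1
CSNK1G1	CK1
VRK1	CK1
MAP2K1	STE
MAP2K2	STE
MAP2K4	STE
MAP3K1	STE
PAK1	STE
PAK2	STE
STK3	STE
STK4	STE
EGFR	TK
ERBB2	TK
SRC	TK
ABL1	TK
INSR	TK
IGF1R	TK
JAK2	TK
SYK	TK
LCK	TK
FYN	TK
MET	TK
RAF1	TKL
BRAF	TKL
ARAF	TKL
IRAK1	TKL
IRAK4	TKL
ILK	TKL
LIMK1	TKL
TGFBR1	TKL
NPR1	RGC
NPR2	RGC
ATM	Atypical
ATR	Atypical
MTOR	Atypical
PDK1	Atypical
PDK2	Atypical
PDK3	Atypical
RIOK1	Atypical
PLK1	Other
AURKA	Other
WNK1	Other
NEK2	Other
CSNK2A1	Other
CSNK2A2	Other
TTK	Other
ULK1	Other
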