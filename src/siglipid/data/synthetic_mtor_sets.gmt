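MTOR_UP	synthetic stand-in up-regulated-on-mTOR-activation set	ACACA	FASN	SCD	SREBF1	HK2	PKM	LDHA	SLC2A1	SLC7A5	SLC3A2	PSAT1	PHGDH	SHMT2	MTHFD2	ATF4	CCND1	HIF1A	VEGFA	EIF4EBP1	NUFIP1
MTOR_DOWN	synthetic stand-in down-regulated-on-mTOR-activation set	CTSD	CTSF	NEU1	HEXA	MAP1LC3B	SQSTM1	ULK1	ATG7	ATG5	GABARAPL1	LAMP1	TFEB	SESN3	KLF15	PPARGC1A	FOXO3	BNIP3	CAT	SOD2	PRKAA2
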