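KLK3	11.8
KLK2	10.4
TMPRSS2	9.6
NKX3-1	8.9
FKBP5	8.2
PMEPA1	7.9
PART1	5.1
ALDH1A3	6.4
NALCN	3.2
GNMT	6.8
ABCC4	7.1
CAMKK2	7.6
EAF2	6.1
ELL2	7.3
HERC3	5.8
MAF	5.4
MED28	6.0
MPHOSPH9	5.2
NNMT	4.1
PTGER4	4.7
SLC45A3	9.2
SORD	7.0
TNK1	4.4
ZBTB10	5.6
ACSL3	8.5
ADAM7	2.6
AZGP1	8.0
CENPN	5.9
PGC	3.8
ABHD2	7.4
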