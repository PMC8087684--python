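symbol	protein_log2FC	transcript_log2FC
NQO1	3.06	1.42
HMOX1	2.48	0.47
FTL	2.34	1.70
TXNRD1	2.33	1.47
SQSTM1	1.59	0.55
FTH1	1.49	1.24
GCLM	1.35	1.16
PRDX1	1.35	1.25
SLC2A1	1.32	1.06
ETFB	0.89	1.24
IDH3A	0.70	1.00
CPB2	0.08	-0.75
CIRBP	-0.94	-0.54
TAGLN	-1.25	-1.56
ITGA1	-1.39	-0.80
UCHL1	-1.73	-1.23
STMN2	-1.96	-1.90
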