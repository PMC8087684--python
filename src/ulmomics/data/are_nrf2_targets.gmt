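ARE_NRF2_TARGETS	published high-confidence ARE promoter-motif genes co-altered in the demo cohort	NQO1	HMOX1	FTL	TXNRD1	SQSTM1	FTH1	GCLM	PRDX1	SLC2A1	ETFB	IDH3A	CPB2	CIRBP	TAGLN	ITGA1	UCHL1	STMN2
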