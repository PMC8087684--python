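FH_SYNTHETIC_LETHALITY_PLACEHOLDER	synthetic stand-in for a published FH synthetic-lethality screen hit list; supply the real catalog as user input	SDHA	SDHB	LDHA	LDHB	ADSL	GOT1	GOT2	MDH1	MDH2	PKM	ENO1	ENO2	PGK1	GAPDH	HK1	HK2	TXN	TXNRD1	GCLC	GCLM
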