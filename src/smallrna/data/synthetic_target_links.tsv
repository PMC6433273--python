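mirna	gene	source
mir-155	FADD	synthetic
mir-155	JARID2	synthetic
mir-155	FOS	synthetic
mir-155	TAB2	synthetic
mir-155	RIPK1	synthetic
mir-155	IKBKE	synthetic
mir-155	PELI1	synthetic
mir-155	MAFB	synthetic
mir-155	JUN	synthetic
mir-155	MYB	synthetic
mir-146a	IRAK1	synthetic
mir-146a	TRAF6	synthetic
mir-146a	NFKB1	synthetic
mir-146a	ERBB2	synthetic
mir-146a	PTGS2	synthetic
mir-9	NFKB1	synthetic
mir-9	IRAK2	synthetic
mir-9	NFAT5	synthetic
mir-9	MYC	synthetic
mir-9	TGFB1	synthetic
mir-147b	IRAK1	synthetic
mir-147b	TRAF6	synthetic
mir-147b	IL6	synthetic
mir-147b	TNFAIP8	synthetic
mir-147b	IL13RA1	synthetic
mir-193a	HMGB1	synthetic
mir-193a	TRIM32	synthetic
mir-193a	NKX3-1	synthetic
mir-193a	PTGS2	synthetic
mir-193a	IL6	synthetic
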