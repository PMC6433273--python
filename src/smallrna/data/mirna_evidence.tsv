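locus	mature	ngs_6h	qpcr_6h	rtpcr_precursor_6h	rtpcr_mature_6h	ngs_24h	qpcr_24h
mir-155	mir-155	yes	yes	yes	yes	yes	yes
mir-146a	mir-146a	yes	yes	yes	yes	yes	yes
mir-9-1	mir-9	yes	yes	not_detected	yes	no	yes
mir-9-2	mir-9	yes	yes	not_detected	yes	yes	yes
mir-187	mir-187	no	no	not_tested	not_tested	yes	yes
mir-146b	mir-146b	no	no	not_tested	not_tested	no	no
mir-449c	mir-449c	yes	no	not_tested	not_tested	no	no
mir-149	mir-149	no	no	not_tested	not_tested	no	no
mir-365b	mir-365b	yes	no	not_tested	not_tested	yes	no
mir-147b	mir-147b	yes	yes	not_detected	yes	yes	yes
mir-193a	mir-193a	yes	no	yes	yes	yes	yes
mir-2116	mir-2116	no	no	not_tested	not_tested	no	no
mir-125a	mir-125a	no	no	not_tested	not_tested	yes	yes
mir-125b1	mir-125b1	no	no	not_tested	not_tested	no	no
mir-99b	mir-99b	no	no	not_tested	not_tested	yes	yes
mir-21	mir-21	no	not_tested	no	no	no	not_tested
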