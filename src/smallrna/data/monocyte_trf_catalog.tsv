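trna_type	position	sequence	trf_name	loci
GlnTTG	5	taatggttagcactctggact	tRF-GlnTTG	tRNA64-GlnTTG(ch6)
GlyGCC	5	tggtggttcagtggtagaatt	tRF-5005	tRNA68-GlyGCC(ch1)
LeuCAG	5	gatggccgagcggtctaaggc	tRF-LeuCAG	tRNA7-LeuCAG(ch6),tRNA17-LeuCAG(ch16),tRNA26-LeuCAG(ch16),tRNA34-LeuCAG(ch1),tRNA36-LeuCAG(ch1),tRNA38-LeuCAG(ch1),tRNA40-LeuCAG(ch1),tRNA42-LeuCAG(ch1),tRNA67-LeuCAG(ch1)
LysCTT	5	gctagctcagtcggtagagca	tRF-LysCTT	tRNA2-LysCTT(ch15),tRNA7-LysCTT(ch16),tRNA9-LysCTT(ch5),tRNA10-LysCTT(ch16),tRNA11-LysCTT(ch5),tRNA13-LysCTT(ch6),tRNA13-LysCTT(ch14),tRNA32-LysCTT(ch16),tRNA119-LysCTT(ch1)
LysTTT	5	gatagctcagtcggtagagca	tRF-LysTTT	tRNA5-LysTTT(ch11)
ValAAC	5	ccgtagtgtagtggtcatcac	tRF-ValAAC	tRNA15-ValAAC(ch5)
ValCAC	5	ctgtagtgtagtggttatcac	tRF-ValCAC	tRNA152-ValCAC(ch6)
GlnTTG	M	actttgaatccagcgatccga	tRF-GlnTTG	tRNA130-GlnTTG(ch6),tRNA173-GlnTTG(ch6),tRNA174-GlnTTG(ch6)
AsnGTT	3	cgaaaggttggtggttcgagc	tRF-AsnGTT	tRNA26-AsnGTT(ch1),tRNA83-AsnGTT(ch1),tRNA107-AsnGTT(ch1),tRNA108-AsnGTT(ch1),tRNA31-AsnGTT(ch17)
AspGTC	3	gggttcgattccccgacgggg	tRF-AspGTC	tRNA69-AspGTC(ch1),tRNA72-AspGTC(ch1),tRNA75-AspGTC(ch1),tRNA78-AspGTC(ch1),tRNA81-AspGTC(ch1),tRNA4-AspGTC(ch12)
GlyGCC	3	attcccggccaatgcacgagt	tRF-3006	tRNA5-GlyGCC(ch16),tRNA24-GlyGCC(ch16),tRNA19-GlyGCC(ch17)
ProAGG	3	caaatcccggacgagcccaca	tRF-ProAGG	tRNA4-ProAGG(ch16)
SerGCT	3	gggttcgaatcccatcctcgt	tRF-SerGCT	tRNA7-SerGCT(ch17),tRNA8-SerGCT(ch11),tRNA62-SerGCT(ch6),tRNA175-SerGCT(ch6)
TrpCCA	3	caaatcacgtcggggtcaaca	tRF-TrpCCA	tRNA168-TrpCCA(ch6)
TyrGTA	3	tggttcgattccggctcgaag	tRF-TyrGTA	tRNA19-TyrGTA(ch14)
ValTAC	3	gggttcgagccccagtggaac	tRF-ValTAC	tRNA16-ValTAC(ch11)
SerTGA	3down	aagcgggtgctcttatttt	tRF-1001	tRNA2-SerTGA(ch10)
ThrAGT	3down	gagcgtccaagctctttccat	tRF-ThrAGT	tRNA4-ThrAGT(ch19)
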