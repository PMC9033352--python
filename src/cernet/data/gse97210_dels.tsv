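# Differentially expressed lncRNAs, atherosclerotic plaque vs control (GSE97210).
gene	logFC	pvalue
PRDM16-DT	7.58	2.39E-10
PART1	7.44	3.27E-11
HAND2-AS1	6.83	7.03E-11
LINC01252	6.33	1.4E-10
PARD3-DT	6.04	1.71E-10
LOC100507334	5.82	1.93E-10
TBX2-AS1	5.69	1.18E-09
SSTR5-AS1	5.48	7.59E-10
PSORS1C3	5.37	4.16E-10
LINC01139	5.08	2.41E-10
SAMMSON	5.06	9.54E-10
LOC100129455	4.96	3.86E-10
LOC105369957	4.93	7.19E-10
LOC105379447	4.88	4.86E-10
LINC00165	4.86	4.01E-10
SPANXA2-OT1	4.83	7.52E-10
TMEM92-AS1	4.75	8.96E-10
GATA6-AS1	4.69	1.25E-09
KIF23-AS1	4.67	5.30E-10
LINC02718	4.64	6.24E-10
FSIP2-AS1	4.53	4.49E-10
HOXC-AS3	4.50	5.78E-10
CNN3-DT	4.12	5.36E-10
LOC100506725	4.10	6.66E-10
LOC105374029	3.98	8.05E-10
LOC100507547	3.93	8.26E-10
LOC100130992	3.87	1.24E-09
SUGCT-AS1	-4.60	4.10E-10
LOC101927602	-4.71	4.78E-10
VPS13A-AS1	-4.73	4.39E-10
C1RL-AS1	-4.76	5.67E-10
LOC105377323	-4.89	3.50E-10
APOC1P1	-5.34	3.49E-10
GAPLINC	-5.44	8.44E-10
LINC00900	-5.84	2.27E-10
L3MBTL4-AS1	-5.93	1.27E-10
LINC01827	-6.27	8.47E-10
CNIH3-AS2	-6.48	4.64E-10
MMP2-AS1	-6.49	1.68E-10
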