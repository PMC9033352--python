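# Centrality of the lncRNA nodes in the published atherosclerotic-plaque ceRNA network.
node	partition	degree	closeness	betweenness
HAND2-AS1	lncRNA	142	0.36317829457364337	0.20723471560902113
LINC00900	lncRNA	72	0.3457564575645757	0.10401877331726586
TBX2-AS1	lncRNA	12	0.20647862494490965	0.021243238559140364
GATA6-AS1	lncRNA	12	0.24657894736842106	0.019403039645996233
SPANXA2-OT1	lncRNA	6	0.22193273330175273	0.002378732808397449
SSTR5-AS1	lncRNA	6	0.2113216057735679	0.006399994526995594
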