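# Centrality of the mRNA nodes in the published atherosclerotic-plaque ceRNA network.
node	partition	degree	closeness	betweenness
CNTN1	mRNA	289	0.4157054125998226	0.42337872101529445
MYOCD	mRNA	226	0.3904166666666667	0.3305499570867205
CNTN4	mRNA	177	0.3781275221953188	0.23587298523512615
FHL5	mRNA	108	0.3557327258921792	0.13106736912407807
DPP4	mRNA	101	0.3538519637462236	0.13660769499759107
IBSP	mRNA	60	0.3322695035460993	0.061990908379872794
CASQ2	mRNA	56	0.33584229390681003	0.07356388148731316
FABP4	mRNA	26	0.30206318504190843	0.024157518050064344
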