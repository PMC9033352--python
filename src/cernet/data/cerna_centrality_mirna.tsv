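# Centrality of the top miRNA nodes in the published atherosclerotic-plaque ceRNA network.
node	partition	degree	closeness	betweenness
hsa-miRNA-570-3p	miRNA	5	0.41644444444444445	0.022132585913046563
hsa-miRNA-466	miRNA	5	0.38783112582781454	0.014465726762748462
hsa-miRNA-4495	miRNA	5	0.380275974025974	0.01051210577447764
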