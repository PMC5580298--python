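contig_id	length_bp	Mara	Elyana	P098	P103
contig_1885	1328	131.23	0.34	57.74	85.39
contig_7159	1479	44.47	0.24	60.64	37.05
contig_12547	2492	26.01	1.75	37.43	33.52
contig_10605	597	48.69	0.67	27.46	114.68
contig_5826	1704	26.52	2.61	42.15	41.24
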