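strain	tnp_count	genome_size_mbp	group	origin
Synechococcus sp. CB0101	15	2.7	coastal	Chesapeake Bay
Synechococcus sp. CB0205	9	2.4	coastal	Chesapeake Bay
Synechococcus sp. RS9917	22	2.6	coastal	Red Sea
Synechococcus sp. WH5701	50	3.0	coastal	Long Island Sound
Synechococcus sp. BL107	0	2.3	marine	Blanes Bay, Mediterranean Sea
Synechococcus sp. CC9311	0	2.6	marine	California Current
Synechococcus sp. CC9902	0	2.2	marine	California Current
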