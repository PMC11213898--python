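organism	plasmid	nat_gene	locus_tag	protein_id	bgc_types	compound
Streptomyces parvulus strain 2297	pSPA1	NAT1	Spa2297_RS32575	WP_079163890.1	NRPS;NRPS-like;T1PKS;Betalactone;Butyrolatone;Other	Polyoxypeptin
Streptomyces sp. Mg1	pSMg1-3	NAT1	M444_RS37885	WP_047961327.1	NRPS-like;T1PKS;Arylpolyene;Butyrolactone;Other	Neocarzinostatin
Streptomyces reticuli TUE45	Plasmid II	NAT1	TUE45_pSRTUE45c_0202	CUW32834.1	T1PKS;T3PKS;Aminocoumarin;Lassopeptide;Nucleoside;Terpene	Rubradirin
Bacillus mycoides strain Gnyt1	Unnamed1	NAT1	B7492_RS30070	WP_061676092.1	CDPS
Paenibacillus cellulositrophicus strain KACC 16577	Unnamed1	NAT1	GCU45_RS30450	WP_152403617.1	NRPS-like
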