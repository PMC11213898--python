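organism	genus	nat_gene	contig_accession	cluster_coordinates	bgc_type	mibig_id	mibig_product	pct_genes_blast_hits
Aspergillus bombycis strain NRRL26010	Aspergillus	NAT2	LYCR01000072.1	10156..56625	T1PKS	BGC0002236	8-Methyldiaporthin	100
Aspergillus flavus AF70	Aspergillus	NAT3	JZDT01000919.1	198365..244830	T1PKS	BGC0002236	8-Methyldiaporthin	100
Aspergillus kawachii IFO 4308	Aspergillus	NAT3	DF126457.1	1..29919	T1PKS	N/A
Aspergillus niger An76	Aspergillus	NAT4	BCMY01000002.1	1137426..1186595	T1PKS	N/A
Aspergillus oryzae RIB40	Aspergillus	NAT3	NW_001884682.1	92784..138782	T1PKS	BGC0002236	8-Methyldiaporthin	100
Aspergillus oryzae 100-8	Aspergillus	NAT3	AMCJ01000103	878641..925106	T1PKS	BGC0002236	8-Methyldiaporthin	100
Aspergillus parasiticus SU-1	Aspergillus	NAT3	JZEE01000186.1	133999..180453	T1PKS	BGC0002236	8-Methyldiaporthin	100
Aspergillus piperis CBS 112811	Aspergillus	NAT1	NW_020291594.1	251331..299010	T1PKS	N/A
Aspergillus pseudotamarii CBS 117625	Aspergillus	NAT1	NW_022475042.1	11899..60965	T1PKS	N/A
Aspergillus udagawae IFM 46973	Aspergillus	NAT3	BBXM01000084.1	68242..116571	T1PKS	BGC0002525	Fusarubin, 1233A, 1233B, NG-391, lucilactaene	28
Penicillium expansum MD-8	Penicillium	NAT1	NW_015971216.1	72103..163635	T1PKS, Terpene	BGC0001338	Citrinin	56
Penicillium nordicum DAOMC 185683	Penicillium	NAT1	LHQQ01000075.1	1..52004	T1PKS	N/A
Penicillium polonicum IBT 4502	Penicillium	NAT1	MDYM01000009.1	157770..250263	NRPS, T1PKS, Terpene	BGC0002710	Metachelin C, A, A-CE, B, dimerumic acid 11-mannoside, dimerumic acid	50
Acremonium chrysogenum ATCC 11550	Acremonium	NAT2	JPKY01000133	1..34441	Indole-T1PKS	N/A
Myceliophthora thermophila ATCC 42464	Myceliophthora	NAT1	CP003002.1	2483801..2485324	NRPS	BGC0002158	Tenuazonic acid	50
Verticillium albo-atrum VaMs.102	Verticillium	NAT1	DS985223.1	1005871..1038902	NRPS-like	N/A
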