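organism	nat_gene	gene_alias	protein_id	proposed_function	bgc_type	mibig_id	bgc_product	product_activity	identity_pct	coverage_pct	most_similar_entry
Amycolatopsis mediterranei strain S699	NAT3	rifF	AAC01715.1	Amide synthase (polyketide cyclization)	PKS	BGC0000136	Rifamycin	Antimicrobial
Salinispora arenicola strain CNS-205	NAT	sare_1251	ABV97156.1	Amide synthase (polyketide cyclization)	PKS	BGC0000137	Rifamycin	Antimicrobial
Streptomyces sp. strain CS	NAT	natF	ADM46361.1	Amide synthase (polyketide cyclization)	PKS	BGC0000106	Naphthomycin A	Antimicrobial, antitumor
Streptomyces sp. strain HKI0576	NAT	divN	CCP20052.1	Amide synthase (polyketide cyclization)	PKS	BGC0001119	Divergolide A-D	Antimicrobial, antitumor
Streptomyces sp. strain LZ35	NAT	hgcF	AFV30252.1	Amide synthase (polyketide cyclization)	PKS	BGC0000075	Hygrocin A,B	Antimicrobial, antitumor
Streptomyces leeuwenhoekii strain C34	NAT2	cxmF	CQR60492.1	Amide synthase (polyketide cyclization)	PKS	BGC0001287	Chaxamycin A-D	Antimicrobial, antitumor
Amycolatopsis sp. strain Hca4	NAT	rmpF	AWH12663.1	Amide synthase (polyketide cyclization)	PKS	BGC0001759	Rifamorpholine A-E	Antimicrobial
Streptomyces spectabilis strain CCTCC M2017417		stvF	ASZ00152.1	Amide synthase (polyketide cyclization)	PKS	BGC0001785	Streptovaricin	Antimicrobial
Amycolatopsis vancoresmycina strain NRRL B-24208	NAT5	kngF	WP_004559807.1	Amide synthase (polyketide cyclization)	PKS	BGC0002009	Kanglemycin A,V1,V2	Antimicrobial
Streptomyces achromogenes subsp. rubradiris strain NRRL 3061		rubF	CAI94702.1	Amide synthase (polyketide cyclization)	PKS	BGC0000141	Rubradirin	Antibiotic
Actinosynnema pretiosum subsp. auranticum strain ATCC 31565		asm9	AAM54087.1	Amide synthase (polyketide cyclization)	PKS	BGC0000020	Ansamitocin P-3	Antitumor
Actinosynnema pretiosum subsp. pretiosum strain ATCC 31280	NAT3	ansa11	AQZ37096.1		PKS	BGC0001511	Ansamitocin P-3	Antitumor	97	99.6	asm9 of BGC0000020
Actinosynnema pretiosum subsp. pretiosum strain ATCC 31280	NAT2	mbcF	ACF35448.1	Amide synthase (polyketide cyclization)	PKS	BGC0000090	Macbecin	Antitumor
Streptomyces hygroscopicus strain NRRL 3602		gdmF	AAO06919.1	Amide synthase (polyketide cyclization)	PKS	BGC0000066	Geldanamycin	Antitumor
Streptomyces hygroscopicus subsp. duamyceticus strain JCM4427		gelD	ABB86411.1		PKS	BGC0000067	Geldanamycin	Antitumor	100	100	gdmF of BGC0000066
Streptomyces hygroscopicus 17997		gdmF	ABI93780.1	Amide synthase (polyketide cyclization)	PKS	BGC0000068	Geldanamycin	Antitumor
Micromonospora sp. strain HK160111	NAT	mas10	ATY46593.1	Amide synthase (polyketide cyclization)	PKS	BGC0001666	Microansamycins A-I	Unknown
Amycolatopsis alba strain DSM 44262	NAT1	asc9	WP_020636846.1	Amide synthase (polyketide cyclization)	PKS	BGC0002011	Ansacarbamitocin A	Antibiotic
Streptomyces nodosus subsp. asukaensis strain ATCC 29757		asuC2	ADI58636.1	N-acyltransferase	T2PKS	BGC0000187	Asukamycin	Antimicrobial, antitumor
Streptomyces aureus SOK1/5-04	NAT	colC2	AIL50169.1	N-acyltransferase	T2PKS	BGC0000213	Colabomycin E	Anti-inflammatory, antibiotic
Streptomyces platensis MA7327		ptmC	ACO31290.1	Arylamine N-acyltransferase (substrates: ADHBA and platensicyl-CoA or platencinyl-CoA)	Terpene	BGC0001140	Platensimycin, platencin	Antibiotic
Streptomyces platensis MA7339		ptnC	ADD82996.1	Arylamine N-acyltransferase (substrates: ADHBA and platencinyl-CoA)	Terpene	BGC0001156	Platencin	Antibiotic
Streptomyces albus subsp. chlorinus strain LW030448		nybK	AYV61412.1	Arylamine N-acyltransferase (substrates: acetoacetyl-CoA and 2,6-diaminophenol)	Other	BGC0001965	Nybomycin	Antibiotic
Streptomyces sp. F001	NAT2	daqS	RZB16698.1	Arylamine N-acyltransferase (substrates: 2,6-DAHQ and beta-ketoacyl-CoA)	Other	BGC0001850	Diazaquinomycin A,E,F,G	Antibiotic, antitumor
Streptomyces sp. F001	NAT3	daqT	RZB16697.1	Arylamine N-acyltransferase (substrates: 2,6-DAHQ and beta-ketoacyl-CoA)	Other	BGC0001850	Diazaquinomycin A,E,F,G	Antibiotic, antitumor
Micromonospora sp. B006	NAT1	daqS	AXO35214.1	Arylamine N-acyltransferase (substrates: 2,6-DAHQ and beta-ketoacyl-CoA)	Other	BGC0001848	Diazaquinomycin H,J	Antibiotic
Micromonospora sp. B006	NAT2	daqT	AXO35215.1	Arylamine N-acyltransferase (substrates: 2,6-DAHQ and beta-ketoacyl-CoA)	Other	BGC0001848	Diazaquinomycin H,J	Antibiotic
Actinomyces sp. Lu 9419	NAT	cetD	ABL74384.1	Aminocyclitol N-acetyltransferase	Cyclitol	BGC0000283	Cetoniacytone A	Antitumor
Streptomyces sp. NRRL B-1347	NAT2	gilW	WP_030684641.1	Putative N-acetyltransferase	Other	BGC0001607	Gilvusmycin	Antibiotic, antitumor
Angiococcus disciformis An d48	NAT	tubG	CAF05656.1	O-acyltransferase	NRPS-PKS	BGC0001053	Tubulysin A	Cytotoxic, anticancer
Streptomyces sp. RI18	NAT	bezG	BBC27534.1	O-acetyltransferase (substrates: PHABA and acetyl-CoA)	Other	BGC0001529	Benzastatin derivatives	Antioxidant
Streptomyces murayamaensis sp. nov. Hata et Ohtani	NAT	orf3	AAO65324.1		PKS	BGC0000236	Kinamycin	Antimicrobial, antitumor	47.0	97.8	bezG of BGC0001529
Streptomyces griseoruber strain Sgr29	NAT	orf2	AQW35032.1		PKS	BGC0001675	Murayaquinone	Antibiotic	40	100.4	nybK of BGC0001965
Streptomyces griseoruber strain Sgr29	NAT	orf23	AQW35053.1		PKS	BGC0001675	Murayaquinone	Antibiotic	43	92.5	orf3 of BGC0000236
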