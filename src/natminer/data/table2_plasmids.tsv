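taxonomic_group	genus	n_species_strains	n_plasmids	n_nat_genes
Actinobacteria	Streptomyces	6	7	8
Actinobacteria	Tsukamurella	1	1	1
Alphaproteobacteria	Ensifer	2	2	2
Alphaproteobacteria	Rhizobium	3	3	3
Alphaproteobacteria	Sinorhizobium	2	2	2
Betaproteobacteria	Caballeronia	2	2	2
Betaproteobacteria	Cupriavidus	3	3	4
Betaproteobacteria	Mycetohabitans	1	1	1
Gammaproteobacteria	Klebsiella	23	23	23
Gammaproteobacteria	Erwinia	1	1	1
Gammaproteobacteria	Pantoea	3	3	3
Gammaproteobacteria	Vibrio	4	4	4
Firmicutes	Bacillus	34	37	59
Firmicutes	Brevibacillus	1	1	1
Firmicutes	Paenibacillus	2	2	3
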