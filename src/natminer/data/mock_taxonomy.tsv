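domain	phylum	class	genus	species	strain
Bacteria	Actinobacteria	Actinomycetia	Streptomyces	coelicolor	SY-101
Bacteria	Actinobacteria	Actinomycetia	Streptomyces	griseus	SY-204
Bacteria	Actinobacteria	Actinomycetia	Amycolatopsis	mediterranea	SY-310
Bacteria	Actinobacteria	Actinomycetia	Mycobacterium	smegmatis	SY-417
Bacteria	Firmicutes	Bacilli	Bacillus	cereus	SY-502
Bacteria	Firmicutes	Bacilli	Bacillus	anthracis	SY-513
Bacteria	Firmicutes	Bacilli	Paenibacillus	polymyxa	SY-528
Bacteria	Proteobacteria	Alphaproteobacteria	Bosea	vestrisii	SY-611
Bacteria	Proteobacteria	Alphaproteobacteria	Bradyrhizobium	oligotrophicum	SY-622
Bacteria	Proteobacteria	Betaproteobacteria	Cupriavidus	campinensis	SY-705
Bacteria	Proteobacteria	Gammaproteobacteria	Pantoea	agglomerans	SY-808
Bacteria	Proteobacteria	Gammaproteobacteria	Klebsiella	pneumoniae	SY-811
Bacteria	Proteobacteria	Gammaproteobacteria	Vibrio	cholerae	SY-823
Bacteria	Bacteroidetes	Flavobacteriia	Flavobacterium	johnsoniae	SY-907
Bacteria	Cyanobacteria	Cyanophyceae	Nostoc	punctiforme	SY-915
Archaea	Euryarchaeota	Halobacteria	Halogeometricum	borinquense	SY-951
Archaea	Euryarchaeota	Halobacteria	Halostella	salina	SY-958
Eukaryota	Ascomycota	Eurotiomycetes	Aspergillus	flavus	SY-970
Eukaryota	Ascomycota	Sordariomycetes	Fusarium	verticillioides	SY-981
Eukaryota	Amoebozoa	Dictyostelia	Dictyostelium	discoideum	SY-992
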