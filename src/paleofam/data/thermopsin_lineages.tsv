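species	genus	family	order	class	phylum	genome_sequenced	hyperthermophile	acidophile	classified	homologue_count	disputed
Thermoplasma acidophilum	Thermoplasma	Thermoplasmataceae	Thermoplasmatales	Thermoplasmata	Euryarchaeota	1	0	1	1	3	0
Thermoplasma volcanium	Thermoplasma	Thermoplasmataceae	Thermoplasmatales	Thermoplasmata	Euryarchaeota	1	1	1	1	1	0
Picrophilus torridus	Picrophilus	Picrophilaceae	Thermoplasmatales	Thermoplasmata	Euryarchaeota	1	1	1	1	1	0
Ferroplasma acidarmanus	Ferroplasma	Ferroplasmaceae	Thermoplasmatales	Thermoplasmata	Euryarchaeota	1	1	1	1	3	1
Sulfolobus acidocaldarius	Sulfolobus	Sulfolobaceae	Sulfolobales	Thermoprotei	Crenarchaeota	1	1	1	1	6	0
Sulfolobus islandicus	Sulfolobus	Sulfolobaceae	Sulfolobales	Thermoprotei	Crenarchaeota	1	1	1	1	7	1
Sulfolobus solfataricus	Sulfolobus	Sulfolobaceae	Sulfolobales	Thermoprotei	Crenarchaeota	1	1	1	1	1	1
Sulfolobus tokodaii	Sulfolobus	Sulfolobaceae	Sulfolobales	Thermoprotei	Crenarchaeota	1	1	1	1	5	1
Acidianus hospitalis	Acidianus	Sulfolobaceae	Sulfolobales	Thermoprotei	Crenarchaeota	1	1	1	1	6	0
Metallosphaera sedula	Metallosphaera	Sulfolobaceae	Sulfolobales	Thermoprotei	Crenarchaeota	1	1	1	1	5	0
Metallosphaera cuprina	Metallosphaera	Sulfolobaceae	Sulfolobales	Thermoprotei	Crenarchaeota	1	1	1	1	2	0
Caldivirga maquilingensis	Caldivirga	Thermoproteaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1	1	1	3	0
Thermoproteus tenax	Thermoproteus	Thermoproteaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1	1	1	3	1
Thermoproteus uzoniensis	Thermoproteus	Thermoproteaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1	1	1	3	1
Thermoproteus neutrophilus	Thermoproteus	Thermoproteaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1		1	1	1
Pyrobaculum sp. 1860	Pyrobaculum	Thermoproteaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1	1	1	1	0
Thermofilum pendens	Thermofilum	Thermofilaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1	1	1	1	0
Vulcanisaeta distributa	Vulcanisaeta	Thermoproteaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1	1	1	0	0
Pyrobaculum aerophilum	Pyrobaculum	Thermoproteaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1	0	1	0	0
Pyrobaculum islandicum	Pyrobaculum	Thermoproteaceae	Thermoproteales	Thermoprotei	Crenarchaeota	1	1	1	1	0	0
Pyrolobus fumarii	Pyrolobus	Pyrodictiaceae	Desulfurococcales	Thermoprotei	Crenarchaeota	1	1	1	1	0	0
Ignicoccus hospitalis	Ignicoccus	Desulfurococcaceae	Desulfurococcales	Thermoprotei	Crenarchaeota	1	1	1	1	0	0
Aeropyrum pernix	Aeropyrum	Desulfurococcaceae	Desulfurococcales	Thermoprotei	Crenarchaeota	1	1	0	1	0	0
Archaeoglobus veneficus	Archaeoglobus	Archaeoglobaceae	Archaeoglobales	Archaeoglobi	Euryarchaeota	1	1	1	1	0	0
Archaeoglobus profundus	Archaeoglobus	Archaeoglobaceae	Archaeoglobales	Archaeoglobi	Euryarchaeota	1	1	1	1	0	0
Methanocaldococcus jannaschii	Methanocaldococcus	Methanocaldococcaceae	Methanococcales	Methanococci	Euryarchaeota	1	1	1	1	0	0
Methanotorris igneus	Methanotorris	Methanocaldococcaceae	Methanococcales	Methanococci	Euryarchaeota	1	1	1	1	0	0
Halobacterium salinarum	Halobacterium	Halobacteriaceae	Halobacteriales	Halobacteria	Euryarchaeota	1	0	0	1	0	0
Methanosarcina mazei	Methanosarcina	Methanosarcinaceae	Methanosarcinales	Methanomicrobia	Euryarchaeota	1	0	0	1	0	0
Thermococcus kodakarensis	Thermococcus	Thermococcaceae	Thermococcales	Thermococci	Euryarchaeota	1	1	0	1	0	0
Pyrococcus furiosus	Pyrococcus	Thermococcaceae	Thermococcales	Thermococci	Euryarchaeota	1	1	0	1	0	0
Nanoarchaeum equitans	Nanoarchaeum				Nanoarchaeota	1	1	0	1	0	0
Candidatus Korarchaeum cryptofilum	Korarchaeum				Korarchaeota	1	1	0	1	0	0
Nitrosopumilus maritimus	Nitrosopumilus	Nitrosopumilaceae	Nitrosopumilales		Thaumarchaeota	1	0	0	1	0	0
Candidatus Micrarchaeum acidiphilum						0	0		0	1	0
Candidatus Parvarchaeum acidophilum						0	0		0	1	0
Candidatus Parvarchaeum acidophilus						0	0		0	1	0
Nanoarchaeote Nst1						0			0	1	0
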