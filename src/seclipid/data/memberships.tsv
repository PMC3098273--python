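organism	genus	type_letters
Actinosynnema mirum DSM 43827	Actinosynnema	M
Agrobacterium vitis S4	Agrobacterium	H
Anabaena variabilis ATCC 29413	Anabaena	F,G
Azotobacter vinelandii DJ	Azotobacter	P
Beijerinckia indica subsp. indica ATCC 9039	Beijerinckia	P
Candidatus Koribacter versatilis Ellin345	Koribacter	R
Candidatus Solibacter usitatus Ellin6076	Solibacter	R
Chitinophaga pinensis DSM 2588	Chitinophaga	N
Chryseobacterium gleum ATCC 35910	Chryseobacterium	N
Clostridium thermocellum ATCC 27405	Clostridium	T
Colwellia psychrerythraea 34H	Colwellia	B
Colwellia sp. MT41	Colwellia	B
Desulfatibacillum alkenivorans AK-01	Desulfatibacillum	C
Desulfobacterium autotrophicum HRM2	Desulfobacterium	S
Desulfococcus oleovorans Hxd3	Desulfococcus	K
Desulfuromonas acetoxidans DSM 684	Desulfuromonas	I
Dinoroseobacter shibae DFL 12	Dinoroseobacter	O
Elusimicrobium minutum Pei191	Elusimicrobium	R
Frankia alni ACN14a	Frankia	M
Frankia sp. CcI3	Frankia	M
Frankia sp. EAN1pec	Frankia	M
Gemmata obscuriglobus UQM 2246	Gemmata	I
Geobacter bemidjiensis Bem	Geobacter	I
Geobacter lovleyi SZ	Geobacter	I
Geobacter sp. FRC-32	Geobacter	I
Geobacter sp. M18	Geobacter	I
Geobacter sp. M21	Geobacter	I
Geobacter uraniireducens Rf4	Geobacter	I
Gloeobacter violaceus PCC 7421	Gloeobacter	O
Microcystis aeruginosa NIES-843	Microcystis	G
Moritella marina	Moritella	B
Moritella sp. PE36	Moritella	B
Nakamurella multipartita DSM 44233	Nakamurella	L
Nodularia spumigena CCY9414	Nodularia	F
Nostoc azollae 0708	Nostoc	F
Nostoc punctiforme PCC 73102	Nostoc	F
Nostoc sp. PCC 7120	Nostoc	F,G
Parvularcula bermudensis HTCC2503	Parvularcula	O
Pelobacter propionicus DSM 2379	Pelobacter	I
Photobacterium profundum 3TCK	Photobacterium	A
Photobacterium profundum SS9	Photobacterium	A
Planctomyces limnophilus DSM 3776	Planctomyces	J
Plesiocystis pacifica SIR-1	Plesiocystis	L
Pseudoalteromonas sp. DS-12	Pseudoalteromonas	A
Psychroflexus torquis ATCC 700755	Psychroflexus	D
Psychromonas ingrahamii 37	Psychromonas	B
Psychromonas sp. CNPT3	Psychromonas	B
Renibacterium salmoninarum ATCC 33209	Renibacterium	M
Rhodococcus erythropolis PR4	Rhodococcus	Q
Roseiflexus castenholzii DSM 13941	Roseiflexus	R
Roseiflexus sp. RS-1	Roseiflexus	R
Saccharophagus degredans 2-40	Saccharophagus	L
Saccharopolyspora erythraea NRRL 2338	Saccharopolyspora	H
Schizochytrium sp. ATCC 20888	Schizochytrium	E
Shewanella amazonensis SB2B	Shewanella	A
Shewanella baltica OS155	Shewanella	A
Shewanella baltica OS185	Shewanella	A
Shewanella baltica OS195	Shewanella	A
Shewanella baltica OS223	Shewanella	A
Shewanella benthica KT99	Shewanella	A
Shewanella denitrificans OS217	Shewanella	A
Shewanella frigidimarina NCIMB 400	Shewanella	A
Shewanella halifaxensis HAW-EB4	Shewanella	A
Shewanella livingstonensis	Shewanella	A
Shewanella loihica PV-4	Shewanella	A
Shewanella oneidensis MR-1	Shewanella	A
Shewanella pealeana ATCC 700345	Shewanella	A
Shewanella piezotolerans WP3	Shewanella	A
Shewanella putrefaciens 200	Shewanella	A
Shewanella putrefaciens CN-32	Shewanella	A
Shewanella sediminis HAW-EB3	Shewanella	A
Shewanella sp. ANA-3	Shewanella	A
Shewanella sp. BR-2	Shewanella	A
Shewanella sp. MR-4	Shewanella	A
Shewanella sp. MR-7	Shewanella	A
Shewanella sp. SCRC-2738	Shewanella	A
Shewanella sp. W3-18-1	Shewanella	A
Shewanella woodyi ATCC 51908	Shewanella	A
Sorangium cellulosum So ce 56	Sorangium	L
Streptomyces avermitilis MA-4680	Streptomyces	M
Streptomyces coelicolor A3(2)	Streptomyces	L
Streptomyces ghanensis ATCC 14672	Streptomyces	L
Ulvibacter sp. SCB49	Ulvibacter	D
Vibrio sp. MED222	Vibrio	A
Vibrio splendidus 12B01	Vibrio	A
Vibrio splendidus LGP32	Vibrio	A
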