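MOLID	molecule_name	OB	DL
MOL013117	4,7-Dihydroxy-5-methoxyl-6-methyl-8-formyl-flavan	37.03	0.28
MOL013118	Neoastilbin	40.54	0.74
MOL013119	Enhydrin	40.56	0.74
MOL013129	(2R,3R)-2-(3,5-dihydroxyphenyl)-3,5,7-trihydroxychroman-4-one	63.17	0.27
MOL001736	taxifolin	60.51	0.27
MOL000358	beta-sitosterol	36.91	0.75
MOL000359	sitosterol	36.91	0.75
MOL004328	naringenin	59.29	0.21
MOL000449	Stigmasterol	43.83	0.76
MOL004567	isoengelitin	34.65	0.7
MOL004575	astilbin	36.46	0.74
MOL004576	taxifolin	57.84	0.27
MOL004580	cis-Dihydroquercetin	66.44	0.27
MOL000546	diosgenin	80.88	0.81
MOL000098	quercetin	46.43	0.28
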