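MOLID	molecule_name	OB	DL
MOL001040	(2R)-5,7-dihydroxy-2-(4-hydroxyphenyl)chroman-4-one	42.36	0.21
MOL001484	Inermine	75.18	0.54
MOL003542	8-Isopentenyl-kaempferol	38.04	0.39
MOL003627	sophocarpine	64.26	0.25
MOL003648	Inermin	65.83	0.54
MOL003673	Wighteone	42.8	0.36
MOL003676	Sophoramine	42.16	0.25
MOL003680	sophoridine	60.07	0.25
MOL000392	formononetin	69.67	0.21
MOL004580	cis-Dihydroquercetin	66.44	0.27
MOL004941	(2R)-7-hydroxy-2-(4-hydroxyphenyl)chroman-4-one	71.12	0.18
MOL005100	5,7-dihydroxy-2-(3-hydroxy-4-methoxyphenyl)chroman-4-one	47.74	0.27
MOL005944	matrine	63.77	0.25
MOL000006	luteolin	36.16	0.25
MOL006561	(+)-14alpha-hydroxymatrine	35.73	0.29
MOL006563	(+)-9alpha-hydroxymatrine	32.04	0.29
MOL006564	(+)-allomatrine	58.87	0.25
MOL006565	AIDS211310	68.68	0.25
MOL006566	(+)-lehmannine	58.34	0.25
MOL006568	isosophocarpine	61.57	0.25
MOL006569	(-)-14beta-hydroxymatrine	37.26	0.29
MOL006570	(-)-9alpha-hydroxysophoramine	35.23	0.29
MOL006571	anagyrine	62.01	0.24
MOL006572	1,4-diazaindan-type,alkaloid,flavascensine	34.64	0.24
MOL006573	13,14-dehydrosophoridine	65.34	0.25
MOL006582	5伪,9伪-dihydroxymatrine	40.93	0.32
MOL006583	7,11-dehydromatrine	44.43	0.25
MOL006596	Glyceollin	97.27	0.76
MOL003347	hyperforin	44.03	0.6
MOL006613	kushenin	47.62	0.38
MOL006619	kushenol J	51.39	0.74
MOL006620	kushenol J_qt	50.86	0.24
MOL006622	kushenol O	42.41	0.76
MOL006623	kushenol,t	51.28	0.64
MOL006626	leachianone,g	60.97	0.4
MOL006627	Lehmanine	62.23	0.25
MOL006628	(+)-Lupanine	52.71	0.24
MOL006630	Norartocarpetin	54.93	0.24
MOL000456	Phaseolin	78.2	0.73
MOL006649	sophranol	55.42	0.28
MOL006650	(-)-Maackiain-3-O-glucosyl-6'-O-malonate	48.69	0.52
MOL006652	trifolrhizin	48.53	0.74
MOL000098	quercetin	46.43	0.28
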