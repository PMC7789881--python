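record_id	name	herb	role	mw	alogp	hdon	hacc	caco2	ob	dl
HJD1	Quercetin	Huanglian	Jun						46.43	0.28
HJD2	Magnograndiolide	Huanglian	Jun						63.71	0.19
HJD3	Palmidin A	Huanglian	Jun						35.36	0.65
HJD4	Corchoroside A_qt	Huanglian	Jun						104.95	0.78
HJD5	Obacunone	Huanglian	Jun						43.29	0.77
HJD6	Palmatine	Huanglian	Jun						64.6	0.65
HJD7	Berberine	Huanglian	Jun						36.86	0.78
HJD8	Coptisine	Huanglian	Jun						30.67	0.86
HJD9	Fagarine	Huanglian	Jun						72.23	0.15
HJD10	Worenine	Huanglian	Jun						45.83	0.87
HJD11	Berberrubine	Huanglian	Jun						35.74	0.73
HJD12	Epiberberine	Huanglian	Jun						43.09	0.78
HJD13	(R)-Canadine	Huanglian	Jun						55.37	0.77
HJD14	Berlambine	Huanglian	Jun						36.68	0.82
HJD15	Moupinamide	Huanglian	Jun						86.71	0.26
HJD16	Ent-Epicatechin	Huangqin	Chen						48.96	0.24
HJD17	EIC	Huangqin	Chen						41.9	0.14
HJD18	Wogonin	Huangqin	Chen						30.68	0.23
HJD19	(2 R)-7-hydroxy-5-methoxy-2-phenylchroman-4-one	Huangqin	Chen						55.23	0.2
HJD20	Beta-sitosterol	Huangqin	Chen						36.91	0.75
HJD21	Sitosterol	Huangqin	Chen						36.91	0.75
HJD22	Stigmasterol	Huangqin	Chen						43.83	0.76
HJD23	Norwogonin	Huangqin	Chen						39.4	0.21
HJD24	5,2′-dihydroxy-6,7,8-trimethoxyflavone	Huangqin	Chen						31.71	0.35
HJD25	Coptisine	Huangqin	Chen						30.67	0.86
HJD26	Supraene	Huangqin	Chen						33.55	0.42
HJD27	Acacetin	Huangqin	Chen						34.97	0.24
HJD28	Methyl linolelaidate	Huangqin	Chen						41.93	0.17
HJD29	Baicalein	Huangqin	Chen						33.52	0.21
HJD30	Diop	Huangqin	Chen						43.59	0.39
HJD31	Epiberberine	Huangqin	Chen						43.09	0.78
HJD32	5,7,2,5-Tetrahydroxy-8,6-dimethoxyflavone	Huangqin	Chen						33.82	0.45
HJD33	Carthamidin	Huangqin	Chen						41.15	0.24
HJD34	2,6,2′,4′-tetrahydroxy-6′-methoxychaleone	Huangqin	Chen						69.04	0.22
HJD35	Dihydrobaicalin_qt	Huangqin	Chen						40.04	0.21
HJD36	Eriodyctiol (flavanone)	Huangqin	Chen						41.35	0.24
HJD37	Salvigenin	Huangqin	Chen						49.07	0.33
HJD38	5,2′,6′-trihydroxy-7,8-dimethoxyflavone	Huangqin	Chen						45.05	0.33
HJD39	5,7,2′,6′-tetrahydroxyflavone	Huangqin	Chen						37.01	0.24
HJD40	Dihydrooroxylin A	Huangqin	Chen						38.72	0.23
HJD41	Skullcapflavone II	Huangqin	Chen						69.51	0.44
HJD42	Oroxylin a	Huangqin	Chen						41.37	0.23
HJD43	Panicolin	Huangqin	Chen						76.26	0.29
HJD44	5,7,4′-trihydroxy-8-methoxyflavone	Huangqin	Chen						36.56	0.27
HJD45	NEOBAICALEIN	Huangqin	Chen						104.34	0.44
HJD46	DIHYDROOROXYLIN	Huangqin	Chen						66.06	0.23
HJD47	Moslosooflavone	Huangqin	Chen						44.09	0.25
HJD48	11,13-Eicosadienoic acid, methyl ester	Huangqin	Chen						39.28	0.23
HJD49	Linolenic acid methyl ester	Huangqin	Chen						46.15	0.17
HJD50	5,7,4′-trihydroxy-6-methoxyflavanone	Huangqin	Chen						36.63	0.27
HJD51	5,7,4′-trihydroxy-8-methoxyflavanone	Huangqin	Chen						74.24	0.26
HJD52	Rivularin	Huangqin	Chen						37.94	0.37
HJD53	bis [(2 S)-2-ethylhexyl] benzene-1,2-dicarboxylate	Huangqin	Chen						43.59	0.35
HJD54	5,8,2′-trihydroxy-7-methoxyflavone	Huangqin	Chen						37.01	0.27
HJD55	Quercetin	Huangbo	Chen						46.43	0.28
HJD56	Beta-sitosterol	Huangbo	Chen						36.91	0.75
HJD57	Stigmasterol	Huangbo	Chen						43.83	0.76
HJD58	Magnograndiolide	Huangbo	Chen						63.71	0.19
HJD59	Oleic acid	Huangbo	Chen						33.13	0.14
HJD60	Palmidin A	Huangbo	Chen						35.36	0.65
HJD61	phellamurin_qt	Huangbo	Chen						56.6	0.39
HJD62	Poriferast-5-en-3beta-ol	Huangbo	Chen						36.91	0.75
HJD63	Kihadalactone A	Huangbo	Chen						34.21	0.82
HJD64	Phellavin_qt	Huangbo	Chen						35.86	0.44
HJD65	Delta 7-stigmastenol	Huangbo	Chen						37.42	0.75
HJD66	Phellopterin	Huangbo	Chen						40.19	0.28
HJD67	Dehydrotanshinone II A	Huangbo	Chen						43.76	0.4
HJD68	Dihydroniloticin	Huangbo	Chen						36.43	0.81
HJD69	Kihadanin A	Huangbo	Chen						31.6	0.7
HJD70	Niloticin	Huangbo	Chen						41.41	0.82
HJD71	Chelerythrine	Huangbo	Chen						34.18	0.78
HJD72	Candletoxin A	Huangbo	Chen						31.81	0.69
HJD73	Hericenone H	Huangbo	Chen						39	0.63
HJD74	Hispidone	Huangbo	Chen						36.18	0.83
HJD75	Campesterol	Huangbo	Chen						37.58	0.71
HJD76	Melianone	Huangbo	Chen						40.53	0.78
HJD77	Phellochin	Huangbo	Chen						35.41	0.82
HJD78	Obacunone	Huangbo	Chen						43.29	0.77
HJD79	Palmatine	Huangbo	Chen						64.6	0.65
HJD80	Fumarine	Huangbo	Chen						59.26	0.83
HJD81	Isocorypalmine	Huangbo	Chen						35.77	0.59
HJD82	Berberine	Huangbo	Chen						36.86	0.78
HJD83	(S)-Canadine	Huangbo	Chen						53.83	0.77
HJD84	Coptisine	Huangbo	Chen						30.67	0.86
HJD85	N-Methylflindersine	Huangbo	Chen						32.36	0.18
HJD86	delta7-dehydrosophoramine	Huangbo	Chen						54.45	0.25
HJD87	Rutaecarpine	Huangbo	Chen						40.3	0.6
HJD88	Skimmianin	Huangbo	Chen						40.14	0.2
HJD89	Fagarine	Huangbo	Chen						72.23	0.15
HJD90	Worenine	Huangbo	Chen						45.83	0.87
HJD91	Cavidine	Huangbo	Chen						35.64	0.81
HJD92	Berberrubine	Huangbo	Chen						35.74	0.73
HJD93	Ptelein	Huangbo	Chen						72.44	0.15
HJD94	Thalifendine	Huangbo	Chen						44.41	0.73
HJD95	Quercetin	Zhizi	Zuo						46.43	0.28
HJD96	EIC	Zhizi	Zuo						41.9	0.14
HJD97	Beta-sitosterol	Zhizi	Zuo						36.91	0.75
HJD98	Kaempferol	Zhizi	Zuo						41.88	0.24
HJD99	Stigmasterol	Zhizi	Zuo						43.83	0.76
HJD100	Oleic acid	Zhizi	Zuo						33.13	0.14
HJD101	Crocetin	Zhizi	Zuo						35.3	0.26
HJD102	Mandenol	Zhizi	Zuo						42	0.19
HJD103	Supraene	Zhizi	Zuo						33.55	0.42
HJD104	METHYL LINOLEATE	Zhizi	Zuo						41.93	0.17
HJD105	(4aS,6 aR,6aS,6bR,8 aR,10R,12 aR,14bS)-10-hydroxy-2,2,6a,6b,9,9,12a-heptamethyl-1,3,4,5,6,6a,7,8,8a,10,11,12,13,14 b-tetradecahydropicene-4a-carboxylic acid	Zhizi	Zuo						32.03	0.76
HJD106	Methyl vaccenate	Zhizi	Zuo						31.9	0.17
HJD107	Ammidin	Zhizi	Zuo						34.55	0.22
HJD108	Isoimperatorin	Zhizi	Zuo						45.46	0.23
HJD109	Exceparl M-OL	Zhizi	Zuo						31.9	0.16
HJD110	Ethyl oleate (NF)	Zhizi	Zuo						32.4	0.19
HJD111	5-Hydroxy-7-methoxy-2-(3,4,5-trimethoxyphenyl)chromone	Zhizi	Zuo						51.96	0.41
HJD112	3-Methylkempferol	Zhizi	Zuo						60.16	0.26
HJD113	GBGB	Zhizi	Zuo						45.58	0.83
HJD114	Sudan III	Zhizi	Zuo						84.07	0.59
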