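P	S	GENE	INH	ZYG	VFS	FH	CLINVAR	DBSNP	MAF	TYPE	ISP	GERP	REFSEQ	VARIANT
FUNCTIONAL VALIDATION REQUIRED
248	F	SCN9A	AD	HT	TRANS	-	-	rs180949263	0.0002	MISS	0.55	3.34	NM_002977.3	c.5672G>A; p.R1891H
		SCN9A	AD	HT		-	B/LB	rs202084411	0.0024	MISS	0.53	4.47	NM_002977.3	c.4612T>C; p.W1538R
		CHD2	AD	HT	MAT	-	-	-	-	MISS	0.53	5.69	NM_001271.3	c.4564G>A; p.D1522N
918	M	MTOR	AD	HT	PAT	-	-	rs1390645065	8.9E-106	MISS	0.52	5.89	NM_004958.3	c.7249G>A; p.V2417M
		MTOR	AD	HT	MAT	-	-	rs201557303	0.0002	MISS	0.42	4.91	NM_004958.3	c.5197G>A; p.A1733T
1084	M	MTOR	AD	HT	PAT	-	-	-	-	MISS	0.51	4.78	NM_004958.3	c.126G>T; p.K42N
1144	M	TSC2	AD	HT	PAT	-	-	-	-	MISS	0.59	5.51	NM_000548.4	c.1724T>C; p.L575P
INCOMPLETE PENETRANCE
754	M	GABRB1	AD	HT	MAT	-	LP	rs1135401786	-	MISS	0.75	3.29	NM_000812.3	c.157C>T; p.R53W
938	F	GABRB1	AD	HT	MAT	-	-	-	-	MISS	0.53	5.43	NM_000812.3	c.775A>G; p.I259V
703	M	SCN2A	AD	HT	PAT	-	-	-	-	MISS	0.67	3.68	NM_001040142.1	c.5551C>T; p.R1851W
801	F	SCN1A	AD	HT	MAT	-	US	rs184524479	0.00019	MISS	0.49	4.33	NM_001165963.1	c.1604G>A; p.R535H
		RBFOX1	AD	HT	MAT	-	-	rs1287710352	8.9E-106	MISS	0.41	5.86	NM_145891.2	c.983A>G; p.K328R
1119	F	SYN1	XL	HT	PAT	-	-	-	-	MISS	0.65	4.88	NM_006950.3	c.718G>A; p.G240R
650	M	FOXG1	AD	HT	PAT	-	-	-	-	MISS	0.63	3.69	NM_005249.4	c.655C>G; p.R219G
1008	M	KCNT1	AD	HT	MAT	-	-	-	-	MISS	NA	4.46	NM_020822.2	c.2912_2913delinsAT; p.(S971N)
268	M	KCNT1	AD	HT	PAT	-	-	-	-	MISS	0.59	3.54	NM_020822.2	c.1421G>T; p.R474L
PLAUSIBLE OLIGOGENIC INHERITANCE
13	M	SCN1A	AD	HT	MAT	-	B/LB	rs121917956	0.002	MISS	0.58	4.89	NM_001165963.1	c.5749C>G; p.R1917G
		CLCN2	AR,AD		PAT	-	LB	rs61729156	0.0068	MISS	0.53	2.83	NM_004366.5	c.203G>A; p.R68H
141	F	SCN1A	AD	HT	PAT	-	-	rs1226308717	-	MISS	0.54	5.44	NM_001165963.1	c.3376A>G; p.N1126D
		SCN1A	AD	HT	PAT	-	B/LB	rs121917956	0.002	MISS	0.58	4.89	NM_001165963.1	c.5782C>G; p.R1928G
		KCNT1	AD	HT	MAT	-	LB	rs148162797	0.0008	MISS	0.57	-7.76	NM_020822.2	c.2220C>G; p.D740E
396	M	SCN1A	AD	HT	NA	-	B/LB	rs121917956	0.002	MISS	0.58	4.89	NM_001165963.1	c.5749C>G; p.R1917G
		CLCN2	AD	HT	NA	-	-	rs202031742	1.5E-105	MISS	0.47	4.07	NM_004366.5	c.368C>T; p.S123F
1113	M	HCN1	AD	HT	NA	-	-	rs1462729387	4.1E-106	MISS	0.45	3.63	NM_021072.3	c.2269A>G; p.T757A
		KCNT1	AD	HT	NA	-	CIP	rs201156458	0.00028	MISS	0.40	4.08	NM_020822.2	c.3256G>A; p.G1086R
		CACNA1H	AD	HT	NA	-	LB	rs187596702	0.00040	MISS	0.49	3.52	NM_021098.2	c.385G>A; p.G129S
968	F	SCN1A	AD	HT	MAT	-	-	-	-	MISS	0.63	5.18	NM_001165963.1	c.2785C>T; p.L929F
		SLC12A5	AD	HT	NA	-	-	-	-	MISS	0.59	3.47	NM_001134771.1	c.3343G>A; p.E1115K
		CACNA1A	AD	HT	PAT	-	US	rs200850308	8.2e-05	MISS	0.56	5.19	NM_023035.2	c.3179G>A
379	F	SCN2A	AD	HT	NA	-	CIP	rs149987700	0.0003	MISS	0.56	5.29	NM_001040142.1	c.952G>A; p.E318K
		SCN7A				-	-	rs146072866	0.001	MISS	0.58	-0.257	NM_002976.3	c.2431A>G; p.S811G
DATA FROM PROGENITORS UNAVAILABLE: DE NOVO MUTATION STATUS UNCONFIRMED
1038	M	SCN8A	AD	HT	NA	+	-	-	-	MISS	0.50	4.96	NM_014191.3	c.4633A>C; p.T1545P
981		HCN1	AD	HT	NA	-	-	-	-	MISS	0.58	5.37	NM_021072.3	c.715G>T; p.V239L
738	F	FOXG1	AD	HT	NA	-	-	-	-	MISS	0.42	1.65	NM_005249.4	c.458G>T; p.G153V
887	M	SCN1A	AD	HT	NA	-	-	rs777120925	7.49e-05	MISS	0.54	4.75	NM_001165963.1	c.1457C>G; p.A486G
		CHRNA4	AD	HT	NA	-	-	-	-	MISS	0.69	5.06	NM_000744.6	c.803C>T; p.P268L
523	F	STXBP1	AD	HT	NA	-	P	rs746172968	8,2E-106	MISS	0.53	5.27	NM_003165.3	c.1756G>A; p.D586N
		SIK1	AD	HT	NA	-	-	-	-	MISS	0.59	3.93	NM_001320643.1	c.1829G>T; p.R610L
676	M	HECW2	AD	HT	NA	-	-	-	-	MISS	0.46	2.43	NM_020760.2	c.3939C>G; p.I1313M
		GABRB1	AD	HT	NA	-	-	-	-	MISS	0.65	1.96	NM_000812.3	c.1017G>C; p.K339N
		GABBR2	AD	HT	NA	-	-	-	-	MISS	0.68	5.64	NM_005458.7	c.1858C>A; p.P620T
1029	M	GRIA3	XLR	HE	NA	-	-	-	-	MISS	0.41	5.52	NM_000828.4	c.793G>A; p.A265T
1099	M	HECW2	AD	HT	NA	-	-	-	-	MISS	0.44	5.10	NM_020760.2	c.900C>A; p.S300R
884	F	ARHGEF9	XL	HT	NA	-	-	-	-	MISS	0.49	5.46	NM_015185.2	c.1454G>T; p.G485V
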