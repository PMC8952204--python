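cohort	snp	gene	trait	risk_allele	raf_V	raf_P	raf_K	raf_pooled	raf_C	raf_catalog	contrasts
Vadu	rs11603334	ARAP1	Fasting blood proinsulin levels	A	0.08	0.25	0.33	0.22	0.12	0.25	V-C;V-K
Vadu	rs1552224	ARAP1	Acute insulin response	A	0.92	0.72	0.67	0.77	0.88	NR	V-K;K-C
Vadu	rs3014246	CCDC17	Apolipoprotein A1 levels	C	0.5	0.39	0.19	0.36	0.5	0.29	V-K;K-C
Vadu	rs682331	NIBAN1	Obesity related traits	G	0.69	0.27	0.2	0.39	0.41	0.44	V-C;V-P;V-K
Vadu	rs3811445	TRIM58	Immature fraction of reticulocytes	G	0.58	0.79	0.39	0.58	0.68	0.58	P-K;K-C
Vadu	rs10922162	ASPM	End-stage coagulation	C	0.72	0.56	0.81	0.7	0.85	0.83	P-K;P-C
Vadu	rs1801222	CUBN	Homocysteine levels	A	0.31	0.03	0.24	0.19	0.09	0.34	P-K;V-P;V-C
Vadu	rs257377	PRKAR2B	LDL cholesterol	G	0.75	0.83	0.97	0.85	0.71	0.79	V-K;K-C
Vadu	rs738409	PNPLA3	Cirrhosis	G	0.28	0.08	0.36	0.24	0.09	0.27	K-C;P-K
NI	rs699	AGT	Mean arterial pressure	A	0.36	0.25	0.11	0.24	0.38	0.48	V-K;K-C
NI	rs2792751	GPAM	HDL cholesterol levels	T	0.16	0.37	0.04	0.19	0.11	0.27	P-K;P-C
NI	rs3764002	WSCD2	Type 2 diabetes, waist-to-hip ratio	C	0.83	0.64	0.56	0.68	0.58	0.72	V-K;V-C
NI	rs3764002	WSCD2	Risk taking tendency, predicted visceral adipose tissue	T	0.17	0.36	0.44	0.32	0.41	0.26	V-K;V-C
NI	rs10793625	WASH2C	Mean corpuscular hemoglobin levels	C	0.67	0.81	0.94	0.81	0.61	0.79	V-K;K-C
NI	rs675531	THEMIS	Recalcitrant atopic dermatitis	C	0.43	0.66	0.33	0.47	0.3	0.11	P-K;P-C
NI	rs8073060	SLFN14	Platelet count	A	0.15	0.44	0.35	0.31	0.44	0.29	V-P;V-C
NI	rs2073498	RASSF1	Feeling worry	A	0.14	0.25	0.06	0.15	0.05	0.11	P-K;P-C
NI	rs41269255	POM121L2	Depressive symptoms	T	0	0.08	0.21	0.1	0.02	0.11	V-K;K-C
NI	rs17412833	HLA-DQB1	Lactate dehydrogenase levels	T	0.2	0.53	0.38	0.37	0.52	0.13	V-P;V-C
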