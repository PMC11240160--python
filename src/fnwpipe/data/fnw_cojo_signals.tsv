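SNP	chr	pos	closest_gene	distance_to_gene	EA	OA	EAF	beta	se	p
rs2284747	1	17306596	MFAP2	0	T	C	0.52	0.04	0.01	1.4E-08
rs2807365	1	22485467	WNT4	15005	G	A	0.32	0.04	0.01	2.5E-08
rs143778922	1	51037660	FAF1	0	GT	G	0.09	0.09	0.01	4.0E-12
rs2820449	1	219714999	SLC30A10	143771	G	A	0.66	0.05	0.01	7.5E-13
rs767282530	2	19727294	OSR1	168880	A	AGATT	0.07	0.08	0.01	9.2E-10
rs7591141	2	42353031	EML4	43460	T	C	0.23	0.05	0.01	3.3E-08
rs57121650	2	71944847	DYSF	30949	T	C	0.52	0.04	0.01	3.2E-08
rs11684985	2	72895293	EXOC6B	0	A	G	0.13	0.06	0.01	1.1E-08
rs75495843	3	38051211	PLCD1	0	A	G	0.03	0.12	0.02	7.2E-10
rs17235557	3	56419866	ERC2	0	T	C	0.67	0.04	0.01	1.5E-08
rs7636776	3	99840446	CMSS1	0	C	T	0.41	0.06	0.01	2.4E-15
rs6763927	3	141140366	ZBTB38	0	T	A	0.44	0.04	0.01	1.2E-08
rs2707450	4	17942560	LCORL	0	C	T	0.26	0.05	0.01	6.0E-10
rs112728585	4	81743389	C4orf22	0	C	A	0.02	0.14	0.03	1.2E-08
rs6824784	4	82275412	RASGEF1B	72136	G	A	0.32	0.05	0.01	8.7E-10
rs2131354	4	145599908	HHIP	0	A	G	0.53	0.07	0.01	1.8E-21
rs1507191	4	151247236	LRBA	0	C	T	0.75	0.05	0.01	6.2E-10
rs77844679	5	170812216	NPM1	1905	G	C	0.82	0.06	0.01	9.1E-10
rs702101	5	171276393	FBXW11	12161	A	G	0.60	0.04	0.01	9.0E-09
rs31778	5	176522036	FGFR4	0	T	C	0.29	0.05	0.01	1.2E-11
rs806790	6	26218920	HIST1H2AE	1209	G	A	0.58	0.04	0.01	1.3E-08
rs112540634	6	34623905	C6orf106	0	T	C	0.14	0.06	0.01	1.5E-08
rs2258604	6	34997606	ANKS1A	0	A	T	0.66	0.05	0.01	1.8E-12
6:35038589_CCT_C	6	35038589	ANKS1A	0	CCT	C	0.98	0.18	0.03	9.0E-10
6:158783382_AT_A	6	158783382	TULP4	0	AT	A	0.33	0.05	0.01	1.7E-10
rs798565	7	2752152	AMZ1	0	G	A	0.70	0.05	0.01	2.9E-11
rs148066163	7	47169380	TNS3	145373	CAA	C	0.28	0.04	0.01	1.6E-08
rs42039	7	92244422	CDK6	0	T	C	0.24	0.06	0.01	2.1E-15
rs34275932	7	120816329	CPED1	0	C	G	0.59	0.04	0.01	1.6E-09
rs149882987	7	148584494	EZH2	3081	G	A	0.03	0.14	0.02	6.3E-11
rs72656010	8	57122215	PLAG1	0	T	C	0.87	0.06	0.01	4.1E-10
rs75810927	8	69587226	C8orf34	0	C	A	0.77	0.05	0.01	1.3E-08
rs9298310	8	79164782	PKIA	263593	G	C	0.29	0.07	0.01	1.5E-22
rs28705285	9	98279801	PTCH1	462	G	T	0.24	0.05	0.01	4.0E-09
rs762624732	9	99106848	SLC35D2	0	T	TA	0.20	0.05	0.01	3.4E-08
rs10123619	9	119353611	ASTN2	0	A	G	0.15	0.06	0.01	5.9E-10
rs10828316	10	22838389	PIP4K2A	0	C	A	0.33	0.05	0.01	3.2E-10
rs3740237	10	32557592	EPC1	0	G	C	0.86	0.06	0.01	8.1E-09
rs12776235	10	95019809	MYOF	46378	T	C	0.53	0.04	0.01	6.7E-09
rs7952436	11	67024534	KDM2A	0	C	T	0.92	0.12	0.01	2.4E-20
rs923346	11	68182375	LRP5	0	T	C	0.83	0.06	0.01	1.5E-09
rs11609223	12	1419127	ERC1	0	G	T	0.68	0.04	0.01	8.5E-09
rs76895963	12	4384844	CCND2	0	G	T	0.02	0.19	0.03	2.4E-12
rs11046703	12	23114157	ETNK1	270558	C	T	0.05	0.10	0.02	8.4E-11
rs59932020	12	24179601	SOX5	75635	T	A	0.22	0.06	0.01	4.3E-12
rs5029277	12	28022055	KLHL42	66082	G	A	0.78	0.07	0.01	5.2E-15
rs11049385	12	28320492	CCDC91	0	G	A	0.31	0.05	0.01	2.2E-12
rs10878984	12	69828534	FRS2	35596	T	C	0.34	0.05	0.01	3.6E-11
rs7954185	12	94096173	CRADD	0	A	T	0.49	0.05	0.01	5.2E-14
rs71190381	13	51120097	DLEU1	0	G	GAGTGA	0.79	0.08	0.01	6.5E-23
rs12889267	14	21542766	ARHGEF40	0	A	G	0.83	0.05	0.01	3.4E-09
rs10083313	14	53917808	DDHD1	297808	A	C	0.27	0.05	0.01	9.1E-10
rs28929474	14	94844947	SERPINA1	0	T	C	0.02	0.14	0.03	3.0E-08
rs569147467	14	103855865	MARK3	0	C	CA	0.33	0.04	0.01	1.4E-08
rs200675402	15	86894913	AGBL1	0	A	AT	0.97	0.13	0.02	2.5E-08
rs8034564	15	99190601	IGF1R	1600	G	A	0.42	0.04	0.01	1.0E-08
rs30224	16	14406119	MKL2	45489	T	C	0.35	0.04	0.01	1.6E-09
rs7223535	17	29211667	ATAD5	0	G	A	0.73	0.05	0.01	2.8E-10
rs1043515	17	36922196	PIP4K2B	0	G	A	0.57	0.05	0.01	2.2E-14
rs9905385	17	59498250	C17orf82	7609	A	G	0.33	0.04	0.01	7.9E-09
rs4141079	17	59531402	TBX4	0	A	C	0.74	0.05	0.01	4.3E-10
rs4968440	17	59613258	TBX4	50787	C	G	0.36	0.04	0.01	3.6E-08
rs17779649	17	70372779	SOX9	250218	A	C	0.87	0.08	0.01	1.2E-15
rs9912553	17	79959703	ASPSCR1	0	G	C	0.72	0.05	0.01	5.5E-10
rs4369779	18	20735408	CABLES1	0	C	T	0.79	0.05	0.01	1.1E-08
rs1074047	19	2158748	AP3D1	0	G	A	0.48	0.05	0.01	2.9E-11
rs742630	20	31350664	DNMT3B	0	C	G	0.60	0.04	0.01	1.2E-08
rs149142833	20	32188142	CBFA2T2	0	C	T	0.84	0.06	0.01	2.3E-09
rs143384	20	34025756	GDF5	0	G	A	0.41	0.10	0.01	4.0E-48
rs6063031	20	45522102	EYA2	1162	A	G	0.45	0.05	0.01	9.0E-13
rs2298333	21	39673981	KCNJ15	0	C	T	0.43	0.04	0.01	1.5E-09
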