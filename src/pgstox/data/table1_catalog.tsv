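# 94 breast-cancer susceptibility variants: per-allele odds ratios, risk-allele
# frequencies and imputation r2 in the genotyped cohort (build-37 positions).
rsid	gene	chr	position	risk_allele	odds_ratio	risk_allele_freq	imputation_r2
rs616488	PEX14	1	10566215	A	1.06	0.67	0.96
rs11552449	PTPN22-BCL2L15-AP4B1-DCLRE1B-HIPK1	1	114448389	T	1.08	0.18	0.94
rs11249433	None	1	121280613	G	1.1	0.43	0.81
rs12405132	RNF115	1	145644984	C	1.05	0.63	1
rs12048493	OTUD7B	1	149927034	C	1.07	0.34	0.52
rs6678914	LGR6	1	202187176	G	1.01	0.40	0.99
rs4245739	MDM4	1	204518842	C	1.03	0.28	1
rs72755295	EXO1	1	242034263	G	1.15	0.04	0.72
rs12710696	OSR1	2	19320803	A	1.04	0.37	1
rs4849887	INHBB	2	121245122	C	1.09	0.92	1
rs2016394	METAP1D-DLX1-DLX2	2	172972971	G	1.05	0.55	0.87
rs1550623	CDCA7	2	174212894	A	1.06	0.85	1
rs1045485	CASP8	2	202149589	G	1.04	0.87	0.99
rs13387042	IGFBP5	2	217905832	A	1.14	0.51	1
rs16857609	DIRC3	2	218296508	T	1.07	0.28	0.99
rs6762644	ITPR1-EGOT	3	4742276	G	1.07	0.41	0.99
rs4973768	SLC4A7	3	27416013	T	1.09	0.49	0.99
rs12493607	TGFBR2	3	30682939	C	1.05	0.34	0.99
rs6796502	PRSS42	3	46866866	G	1.09	0.91	0.96
rs1053338	ATXN7	3	63967900	G	1.08	0.15	0.99
rs9790517	TET2	4	106084778	T	1.05	0.20	0.99
rs6828523	ADAM29	4	175846426	C	1.1	0.89	1
rs10069690	TERT	5	1279790	T	1.02	0.25	0.66
rs7726159	TERT	5	1282319	A	1.04	0.36	0.75
rs2736108	TERT	5	1297488	C	1.07	0.73	0.78
rs13162653	MARCH11	5	16187528	G	1.05	0.57	0.97
rs2012709	SUB1	5	32567732	T	1.05	0.49	0.99
rs10941679	None	5	44706498	G	1.12	0.26	0.95
rs889312	MAP3K1	5	56031884	C	1.12	0.30	0.99
rs10472076	RAB3C	5	58184061	C	1.04	0.38	0.94
rs1353747	PDE4D	5	58337481	T	1.09	0.89	0.99
rs7707921	ATG10	5	81538046	A	1.08	0.75	0.99
rs1432679	EBF1	5	158244083	G	1.07	0.44	0.99
rs11242675	FOXQ1	6	1318878	T	1.06	0.63	0.99
rs204247	RANBP9	6	13722523	G	1.05	0.45	1
rs9257408	None	6	28926220	C	1.05	0.37	0.98
rs17529111	None	6	82128386	G	1.05	0.22	0.98
rs12662670	ESR1	6	151918856	G	1.14	0.09	0.99
rs2046210	ESR1	6	151948366	A	1.05	0.38	1
rs6964587	AKAP9	7	91630620	T	1.05	0.40	1
rs4593472	LINC-PINT	7	130667121	C	1.05	0.64	1
rs720475	ARHGEF5-NOBOX	7	144074929	G	1.06	0.74	1
rs9693444	None	8	29509616	A	1.07	0.35	0.99
rs13365225	KCNU1	8	36858483	A	1.05	0.84	1
rs6472903	CASC9	8	76230301	T	1.1	0.84	0.93
rs2943559	HNF4G	8	76417937	G	1.13	0.09	1
rs13267382	None	8	117209548	A	1.05	0.36	0.93
rs13281615	MYC	8	128355618	G	1.1	0.43	0.99
rs11780156	MYC	8	129194641	T	1.07	0.19	1
rs1011970	CDKN2A/B	9	22062134	T	1.05	0.18	0.99
rs10759243	KLF4	9	110306115	A	1.05	0.29	1
rs865686	KLF4	9	110888478	T	1.11	0.64	0.99
rs2380205	ANKRD16	10	5886734	C	1.02	0.57	1
rs7072776	MLLT10-DNAJC1	10	22032942	A	1.06	0.30	1
rs11814448	DNAJC1	10	22315843	C	1.22	0.02	0.98
rs10995190	NRBF2	10	64278682	G	1.17	0.87	0.99
rs704010	ZMIZ1	10	80841148	T	1.07	0.42	1
rs7904519	TCF7L2	10	114773927	G	1.06	0.48	0.99
rs11199914	FGFR2	10	123093901	C	1.06	0.70	0.99
rs2981579	FGFR2	10	123337335	A	1.25	0.44	0.99
rs3817198	LSP1	11	1909006	C	1.07	0.34	1
rs3903072	DKFZp761e198-OVOLI-SNX32-CFL1-MUS81	11	65583066	G	1.06	0.56	1
rs78540526	CCND1	11	69331418	T	1.18	0.08	0.98
rs554219	CCND1	11	69331642	G	1.12	0.13	0.99
rs75915166	CCND1	11	69379161	A	1.024	0.07	0.95
rs11820646	BARX2	11	129461171	C	1.05	0.60	0.99
rs12422552	None	12	14413931	C	1.03	0.29	0.91
rs10771399	PTHLH	12	28155080	A	1.16	0.89	0.99
rs17356907	NTN4	12	96027759	A	1.1	0.72	1
rs1292011	None	12	115836522	A	1.08	0.58	1
rs11571833	BRCA2-N4BP2LI-N4BP2L2	13	32972626	T	1.26	0.01	0.99
rs2236007	PAX9-SLO25A21	14	37132769	G	1.09	0.81	0.98
rs2588809	RAD51L1	14	68660428	T	1.07	0.17	1
rs999737	RAD51L1	14	69034682	C	1.08	0.76	0.99
rs941764	CCDC88C	14	91841069	G	1.06	0.35	0.99
rs11627032	RIN3	14	93104072	T	1.06	0.76	0.99
rs3803662	TOX3	16	52586341	A	1.23	0.30	1
rs17817449	MIRI972-2-FTO	16	53813367	T	1.08	0.61	0.99
rs11075995	FTO	16	53855291	T	1.04	0.24	0.99
rs13329835	CDYL2	16	80650805	G	1.08	0.23	0.99
rs146699004	TEFM	17	29230520	GGT	1.08	0.81	0.87
rs6504950	COX11	17	53056471	G	1.07	0.72	1
rs745570	CBX8	17	77781725	A	1.05	0.50	1
rs527616	None	18	24337424	G	1.04	0.66	0.94
rs1436904	CHST9	18	24570667	T	1.06	0.60	1
rs6507583	SETBP1	18	42399590	A	1.10	0.93	0.99
rs8170	ABHD8/ANKLE1	19	17389704	A	1.03	0.20	0.99
rs2363956	ABHD8/ANKLE1	19	17394124	T	1.03	0.51	0.96
rs4808801	SSBP4-ISYNA1-ELL	19	18571141	A	1.07	0.66	1
rs3760982	C19orf61-KCNN4-LYPD5-ZNF283	19	44286513	A	1.06	0.49	0.99
rs2823093	NRIP1	21	16520832	G	1.08	0.75	0.97
rs17879961	CHEK2	22	29121087	G	1.36	0.001	0.86
rs132390	EMID1-RHBDD3-EWSR1	22	29621477	C	1.11	0.04	0.78
rs6001930	MKL1	22	40876234	C	1.13	0.10	1
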