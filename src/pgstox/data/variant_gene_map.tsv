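# Best-effort variant-to-gene assignment for the 94-variant catalog, used to
# rank genes for enrichment. Intergenic variants keep a chr_pos locus label;
# override with your own mapping for serious use.
rsid	gene
rs616488	PEX14
rs11552449	DCLRE1B
rs11249433	chr1_121280613
rs12405132	RNF115
rs12048493	OTUD7B
rs6678914	LGR6
rs4245739	MDM4
rs72755295	EXO1
rs12710696	OSR1
rs4849887	INHBB
rs2016394	DLX2
rs1550623	CDCA7
rs1045485	CASP8
rs13387042	IGFBP5
rs16857609	DIRC3
rs6762644	ITPR1
rs4973768	SLC4A7
rs12493607	TGFBR2
rs6796502	PRSS42
rs1053338	ATXN7
rs9790517	TET2
rs6828523	ADAM29
rs10069690	TERT
rs7726159	TERT
rs2736108	TERT
rs13162653	MARCH11
rs2012709	SUB1
rs10941679	chr5_44706498
rs889312	MAP3K1
rs10472076	RAB3C
rs1353747	PDE4D
rs7707921	ATG10
rs1432679	EBF1
rs11242675	FOXQ1
rs204247	RANBP9
rs9257408	chr6_28926220
rs17529111	chr6_82128386
rs12662670	ESR1
rs2046210	ESR1
rs6964587	AKAP9
rs4593472	LINC
rs720475	ARHGEF5
rs9693444	chr8_29509616
rs13365225	KCNU1
rs6472903	CASC9
rs2943559	HNF4G
rs13267382	chr8_117209548
rs13281615	MYC
rs11780156	MYC
rs1011970	CDKN2A
rs10759243	KLF4
rs865686	KLF4
rs2380205	ANKRD16
rs7072776	MLLT10
rs11814448	DNAJC1
rs10995190	NRBF2
rs704010	ZMIZ1
rs7904519	TCF7L2
rs11199914	FGFR2
rs2981579	FGFR2
rs3817198	LSP1
rs3903072	SNX32
rs78540526	CCND1
rs554219	CCND1
rs75915166	CCND1
rs11820646	BARX2
rs12422552	chr12_14413931
rs10771399	PTHLH
rs17356907	NTN4
rs1292011	chr12_115836522
rs11571833	BRCA2
rs2236007	PAX9
rs2588809	RAD51L1
rs999737	RAD51L1
rs941764	CCDC88C
rs11627032	RIN3
rs3803662	TOX3
rs17817449	FTO
rs11075995	FTO
rs13329835	CDYL2
rs146699004	TEFM
rs6504950	COX11
rs745570	CBX8
rs527616	chr18_24337424
rs1436904	CHST9
rs6507583	SETBP1
rs8170	ANKLE1
rs2363956	ANKLE1
rs4808801	SSBP4
rs3760982	KCNN4
rs2823093	NRIP1
rs17879961	CHEK2
rs132390	EMID1
rs6001930	MKL1
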