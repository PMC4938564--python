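# Top half (38 of 76) of the gene list ranked by each gene's most significant
# variant-level association with neutropenia (per-allele OR and p-value).
gene	rsid	odds_ratio	p_value
ZMIZ1	rs704010	1.20	0.02
KCNN4	rs3760982	0.85	0.03
MAP3K1	rs889312	1.19	0.04
DCLRE1B	rs11552449	0.81	0.05
KCNU1	rs13365225	0.81	0.05
DLX2	rs2016394	0.86	0.06
ITPR1	rs6762644	1.15	0.08
MYC	rs13281615	1.14	0.10
RANBP9	rs204247	1.13	0.10
CBX8	rs745570	0.89	0.13
SNX32	rs3903072	0.90	0.17
SLC4A7	rs4973768	1.11	0.18
TET2	rs9790517	0.89	0.22
KLF4	rs10759243	1.10	0.23
TERT	rs2736108	0.89	0.26
ANKRD16	rs2380205	0.92	0.27
CDYL2	rs13329835	0.90	0.27
NRIP1	rs2823093	0.91	0.29
CHST9	rs1436904	0.93	0.34
CCND1	rs78540526	1.14	0.37
FGFR2	rs2981579	1.07	0.37
DNAJC1	rs11814448	0.74	0.37
HNF4G	rs2943559	0.88	0.38
ATXN7	rs1053338	0.91	0.38
AKAP9	rs6964587	1.07	0.38
MKL1	rs6001930	0.90	0.41
LGR6	rs6678914	1.06	0.45
FOXQ1	rs11242675	0.94	0.46
ANKLE1	rs8170	1.07	0.50
RNF115	rs12405132	0.95	0.51
SETBP1	rs6507583	1.10	0.52
ADAM29	rs6828523	0.92	0.52
NRBF2	rs10995190	0.93	0.53
ESR1	rs12662670	0.92	0.53
CHEK2	rs17879961	1.36e-19	0.54
PTHLH	rs10771399	0.93	0.56
IGFBP5	rs13387042	0.96	0.59
MDM4	rs4245739	0.96	0.60
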