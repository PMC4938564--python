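p53_signalling	cell-cycle arrest and apoptosis downstream of p53	TP53	MDM2	MDM4	CHEK1	CHEK2	ATM	ATR	CCND1	CCND2	CDKN1A	CDKN2A	CASP8	GADD45A
dna_crosslink_repair	inter-strand crosslink and double-strand break repair	BRCA2	CHEK2	EXO1	DCLRE1B	MUS81	RAD51L1	ATM	XRCC2	FANCA
estrogen_response	estrogen-receptor signalling and targets	ESR1	FGFR2	CCND1	MAP3K1	ZMIZ1	IGFBP5	TOX3	LSP1
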