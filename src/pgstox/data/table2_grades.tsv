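# Observed toxicity grade distributions (counts) in the genotyped cohort.
# Neutropenia graded 0-4 over 1676 patients; taxane sensory neuropathy graded 0-3
# over 1279 patients (NCI CTCAE v2/3). Case definitions: neutropenia grade >=3,
# neuropathy grade >=2.
phenotype	grade	count
neutropenia	0	733
neutropenia	1	199
neutropenia	2	245
neutropenia	3	293
neutropenia	4	206
neuropathy	0	271
neuropathy	1	648
neuropathy	2	304
neuropathy	3	56
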