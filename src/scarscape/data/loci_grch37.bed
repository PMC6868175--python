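# Default locus pairs for enhancer/gene copy-ratio analysis (GRCh37).
# Boundaries are approximate and editable: chrom, 0-based start, end, pair, role.
X	66128000	66133000	AR	enhancer
X	66764464	66950461	AR	gene
8	128025398	128033259	MYC	enhancer
8	128748314	128753680	MYC	gene
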