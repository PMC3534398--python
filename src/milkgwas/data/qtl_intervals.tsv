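chrom	start_bp	end_bp	trait_class	source
4	57000000	75300000	MSPD	holstein
6	99200000	113000000	MSPD	french_dairy
7	35900000	106000000	MSPD	holstein
8	20000000	55100000	MSPD	french_dairy
19	51500000	53500000	MSPD	french_dairy
23	19400000	28000000	MSPD	finnish_ayrshire
23	19400000	36700000	MSPD	finnish_ayrshire
6	34600000	44200000	UT	holstein
15	40100000	47900000	UT	holstein
25	39100000	41100000	UT	holstein
6	41400000	43400000	SCS	holstein_friesian
15	39100000	41100000	SCS	holstein
25	39100000	41100000	SCS	holstein
6	26700000	65900000	CM	holstein_friesian
25	32900000	43900000	MY	brown_swiss
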