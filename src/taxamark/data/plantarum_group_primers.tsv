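# Published mutL-targeting PCR primers for the Lactiplantibacillus plantarum
# species group: one group-level degenerate pair and four species-specific
# diagnostic pairs with their reported amplicon sizes (bp).
assay	target	forward	reverse	expected_product
LpmutL	group	TSGAYGTSAAYGTKCAYCC	ATGYGGRCARTTRAANGGAT	1000
spLarg	L. argentoratensis	CCTTTGGTGAACCCGCTGAA	AGTTCGGCTAATAGTGGCAA	319
spLpara	L. paraplantarum	TCAGGTGGCGGATAAGACTAC	GGTTGCCGAMGTGGCGTCA	115
spLpen	L. pentosus	CCTCCGCTGAACCAATCATG	TTCAGGACATCACTGGTGGG	385
spLplan	L. plantarum	GCGRTTGTTCCGTCAGAAT	CTTGCAGCCGTGCTGGTTT	176
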