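# Example 16S rRNA amplicon primer pairs (IUPAC, 5'->3').
# These are widely used survey primers, shipped as editable examples.
# name	forward	reverse	max_mismatches	min_len	max_len
515F_806R	GTGYCAGCMGCCGCGGTAA	GGACTACNVGGGTWTCTAAT	0	200	500
341F_805R	CCTACGGGNGGCWGCAG	GACTACHVGGGTATCTAATCC	0	300	600
27F_1492R	AGAGTTTGATCMTGGCTCAG	TACGGYTACCTTGTTACGACTT	0	1200	1600
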