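CHROM	POS	ID	REF	ALT	AD
bgc	15246	insertion_1	.	+GGAGGATGGGGTGGAGGATGGGGTGGAGGATGGGGTGGAGGATGGGGTGGAGGATGGGGT	7,15
bgc	24776	insertion_2	.	+GGGGTCGGATGGGGGGTCGGATGG	8,57
bgc	67976	insertion_3	.	+GCGGCGGTTGAGGCGGAGGCGGCGGTTGAGGCGGAGGCGGCGGTTGAGGCGGAG	23,164
bgc	93995	snp_1	C	T	363,457
bgc	95154	snp_2	A	G	175,621
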