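sample	breakpoint_a	breakpoint_b	primer_a	primer_b	orientation	probe	annealing_temp_C
S1	[chr22:29288203]G	T [chr11:128806738]	AGTTCTTCTGTATGGAGAGAGGT	TGATGGTACTGAGGCTGTGG	fwd	ACCAGGAAGCAGCTGATCTT	58
S97	[chr22:29292655]T	G [chr11:128795030]	TGTGGGGTTGTTAAGGTCAGT	TTGAAACAGGGCCTCACTCT	fwd	TTTAAACCACAGAGTGCGCC	58
S69	G [chr22:29289258]	[chr11:128777239] A	CAGTAGGAAGTGAGCCCATAAT	TCGAAGAAACGGAGGGCG	rev	ACTATAGCCTGAGGTGCACC	58
S121	G [chr22:29288035]	[chr11:128796041] A	GTGTTTTGGTTACCTCTCTCCA	CCCCTGCCAAGTATCTACCT	rev	CCTCCTCACAGAATATTTGCAGT	58
S101	C [chr22:29287795]	[chr11:128786094] G	TCTCAAGTGATCCTCCTGCC	CTGATGCCCAAGTGCCAAAA	rev	ATTCAGAACCTCGTGGGGAG	55
S70	C [chr22:29287723]	[chr11:128797267] T	TGACTGATAGGGAGGCCAAA	CGTGAATCCAAGACCACAGAC	rev	TGGGGAAGTTGTATGCAGTGA	55
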