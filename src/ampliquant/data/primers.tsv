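gene	forward	reverse	amplicon_len
Bgn	TGCCATGTGTCCTTTCGGTT	CAGGTCTAGCAGTGTGGTGTC	112
Col1a1	GCTCCTCTTAGGGGCCACT	CCACGTCTCACCATTGGGG	103
Col3a1	ACGTAGATGAATTGGGATGCAG	GGGTTGGGGCAGTCTAGTG	154
Col5a1	TGAGTCTGGTTTTCCCGAGGA	GCCCTGCTCATTGTAAATGGAGA	97
Col12a1	AAGTTGACCCACCTTCCGAC	GGTCCACTGTTATTCTGTAACCC	111
Dcn	AAGCTGCGGAAATCCGACTTC	CCCAGAGTTTTTCAGTGGGTTG	81
Eef1a1	TACGCCTGGGTCTTAGACAAA	TCCACAGGGAGATGTCAATAGT	70
Fn1	GGAGGAAGCCGGGGTTTTAAC	GCGCTCATAAGTGTCACCCA	105
Lum	CTCTTGCCTTGGCATTAGTCG	GGTCATCACAGTACATGGCAGT	147
Mkx	CACCGTGACAACCCGTACC	GCACTAGCGTCATCTGCGAG	73
Mmp2	CAAGTTCCCCGGCGATGTC	TTCTGGTCAAGGTCACCTGTC	171
Mmp3	ACATGGAGACTTTGTCCCTTTTG	TTGGCTGAGTGGTAGAGTCCC	192
Mmp14	CAGTATGGCTACCTACCTCCAG	GCCTTGCCTGTCACTTGTAAA	119
Mmp16	TTACTCGCATTCAGCTCTGGA	CCGCAGACTGTAGCACATAAAA	101
Scx	CTGGCCTCCAGCTACATTTCT	GTCACGGTCTTTGCTCAACTT	237
Serpine1	TTCAGCCCTTGCTTGCCTC	ACACTTTTACTCCGAAGTCGGT	116
Timp2	TCAGAGCCAAAGCAGTGAGC	GCCGTGTAGATAAACTCGATGTC	142
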