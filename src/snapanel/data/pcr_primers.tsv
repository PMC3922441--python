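locus	covered_rsids	fwd_seq	rev_seq	reaction	amplicon_len	conc_uM	seq_primer	seq_primer_conc_uM
BCL11A	rs11886868,rs766432	CACACCATGGATGAATCCCAGA	TGGTGCTACCCTGAAAGACGG	B	441	0.1
BCL11A	rs4671393,rs7557939	CCTTGTTTACAGAGGGGCAACC	GCCTTGGGAAGAAAGACAGCAT	B	649	0.4
BCL11A	rs6732518	TGGGTGACCCTCTGACTCCT	GCTTTAACGCACTACACCCCAC	A	69	0.1
BCL11A	rs10189857	AGCCATGGTCCACCCACAGA	TTCCAGGTCCCCCAGAAGTAGC	B	411	0.1
BCL11A	rs6545816	GGTTGATGAGAAAATTACCGCATTA	AACGAGGGTGTTCAAAGTAACCA	A	103	0.3
BCL11A	rs7599488,rs1427407	CTGGCCGGGAGCATTTCAA	TTTAACCTTCTTAGCACCCACAAA	B	515	0.6	GCACAGCATGTGACATGATATTC	0.5
BCL11A	rs10184550	CCTGATCTCTGATTGTTGCTTTGA	TGTACCACCAGAAGTCCTGGAAA	A	120	0.4
BCL11A	rs7606173	ACACCCTGTGATCTTGTGG	GCCAACAGTGATAACCAGC	A	201	0.8
BCL11A	rs6706648	GAAGCTTCCCCTGTCTGCA	TGAGTGCGTATTTGTAAAGTTCC	A	333	0.6
HBS1L-MYB	rs28384513	CCTTGAGCTACCTACGCCAG	CTTTCTCAGATTATCAGGAACCAAATTT	A	66	0.4	GCCCACTGTGTGCTTAATGAAA	0.5
HBS1L-MYB	rs7776054,rs9399137	ATATGCAATATTTGTAATTTGTGTTCTGC	TTAACTATATCTGTGCACAGAAATACAG	B	190	0.8
HBS1L-MYB	rs9389268,rs9402685	TGCAACCTCCGCTTCCA	TAGCTCACACCTGTAATCATGC	A	221	0.2
HBS1L-MYB	rs4895441,rs4895440	GGAAACCAGTTTAGAAAGCGTGG	TCTCTCTGGATCTCCCTGTC	B	122	0.3
HBS1L-MYB	rs6929404	GCAGTGAGATTTCTATTATTAGGCTC	CTGACTAAACTTCTAATCAAAGGCAT	B	136	0.3
HBS1L-MYB	rs9402686	GAGCAGAGAAGTTTAAAGTGTGTG	TGGACAAAACTGCCCTTTGTC	B	150	0.4
HBS1L-MYB	rs1320963	ATGGCTTGGTAAGGACTTAAGAG	CCTGAGAGTTCTTTTGGGATCTT	B	60	0.4	TTCAACTTTCCACTGAGTTTTCG	0.5
HBS1L-MYB	rs6904897	ATCCAGGCTTGCCAAATATACCT	GACTTGCCTGTGCTGGAAATT	A	99	0.3
HBS1L-MYB	rs35959442	TGACCCAGAGCGTCCAAG	GTTACATCTGCAGCTGACACC	A	160	0.8
HBS1L-MYB	rs9376090	GATATGGCCAATACCATATGAAGCTAA	AGCTGGGCCTCATTTGTTC	B	81	0.2
HBS1L-MYB	rs9494142	AGGAAGTGTCTTTGGTCTCTCAG	TGAGACTCCATCTCAAAAAACAACA	A	143	0.4
HBS1L-MYB	rs11759553	TTGCCAGGCTGTCTTGCA	GTTCTGCAGGGTCCTTTGG	B	107	0.2
HBS1L-MYB	rs6934903	CCTTGGCCCACATCGCT	TAGAACCTGAAACAGTACTCCACA	A	130	0.2
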