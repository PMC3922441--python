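locus	rsid	direction	strand	primer_seq	size_bp	conc_uM	detected_alleles
BCL11A	rs11886868	F	minus	CAGAATCATTCTGCTCTGTG	20	0.02	G/A
BCL11A	rs4671393	F	minus	acaaGGAATCTTAATTTCCTGCAC	24	0.1	T/C
BCL11A	rs7557939	F	minus	aaCACCCTCTCTCACTCTTG	20	0.1	C/T
BCL11A	rs6732518	F	minus	aactaggtgccacgtcgtgaaagtctgacaaGACTCCTGAGAGCATGT	48	0.02	G/A
BCL11A	rs10189857	F	minus	gtctgacaaGCTTGTCACAGTTCTCTAC	28	0.2	T/C
BCL11A	rs6545816	F	minus	tctgacaaATTAAAATTAAGCCTCTTGCTTTT	32	0.05	T/G
BCL11A	rs7599488	R	minus	aactgactaaactaggtgccacgtcgtgaaagtctgacaaTTAGTCTCAGCCACCTG	57	0.2	G/A
BCL11A	rs1427407	F	minus	gtctgacaaTTCAAGTAGATATCAGAAGGGAA	32	0.1	A/C
BCL11A	rs766432	F	minus	aggtgccacgtcgtgaaagtctgacaaATGAATGACTTTTGTTGTATGTAAA	52	0.05	G/T
BCL11A	rs10184550	F	minus	ctgacaaTTGCTTTGATAAGTATCTATACAAATATT	36	0.05	C/T
BCL11A	rs7606173	F	minus	taggtgccacgtcgtgaaagtctgacaaTGTCCTGTGAGCGGTC	44	0.2	C/G
BCL11A	rs6706648	F	minus	acgtcgtgaaagtctgacaaCTTGCCTCCCCCTGAC	36	0.05	G/A
HBS1L-MYB	rs28384513	F	plus	aggtgccacgtcgtgaaagtctgacaaTACCTACGCCAGCGTTC	44	0.15	T/G
HBS1L-MYB	rs7776054	F	plus	actaggtgccacgtcgtgaaagtctgacaaCAATATTTGTAATTTGTGTTCTGCTTCTAC	60	0.1	A/G
HBS1L-MYB	rs9399137	F	plus	CAATAATGTAATTAACTGAACATATGGTTATT	32	0.15	T/C
HBS1L-MYB	rs9389268	F	plus	GATTACAGGCGCATGCAACC	20	0.3	A/G
HBS1L-MYB	rs4895441	R	plus	actgactaaactaggtgccacgtcgtgaaagtctgacaaCTTACTCAGTTCTCTGCTCATGTA	63	0.1	A/G
HBS1L-MYB	rs6929404	F	plus	gtgaaagtctgacaaAAAAGTCTAGAGCACAAAAATTAAAATAA	44	0.1	C/A
HBS1L-MYB	rs9402686	F	plus	GTTTAAAGTGTGTGACCTTGAGAC	24	0.05	G/A
HBS1L-MYB	rs1320963	R	plus	agtctgacaaCTGAGAGTTCTTTTGGGATCTTTCAC	36	0.05	A/G
HBS1L-MYB	rs6904897	R	plus	tcaggtgccacgtcgtgaaagtctgacaaGTGTATTTCTTTTGGTTGTGCATACA	55	0.1	T/G
HBS1L-MYB	rs35959442	R	plus	gtctgacaaGCTCTTATAGCAGTCTACAGCAG	32	0.05	C/G
HBS1L-MYB	rs9376090	F	plus	AGTCTAGCTGAGTGTTAGCC	20	0.05	T/C
HBS1L-MYB	rs4895440	F	plus	GCGTGGCTGGGGAAAG	16	0.1	A/T
HBS1L-MYB	rs9494142	F	plus	ccacgtcgtgaaagtctgacaaCAGTCAATTCGATTCTACTACTGACA	48	0.05	T/C
HBS1L-MYB	rs9402685	F	plus	ccccccaactgactaaactaggtgccacgtcgtgaaagtctgacaaATGTTTCACCGTGTTGCTCAGG	68	0.1	T/C
HBS1L-MYB	rs11759553	F	plus	aaagtctgacaaTGATTGGGGTAGGCCATAGG	32	0.05	A/T
HBS1L-MYB	rs6934903	F	plus	tcaggtgccacgtcgtgaaagtctgacaaCCTGCATAAGTGTCGAATCTCTA	52	0.05	T/A
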