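rsid	chrom	pos	ref	alt	locus
rs11886868	2	60720246	C	T	BCL11A
rs4671393	2	60720951	A	G	BCL11A
rs7557939	2	60721347	G	A	BCL11A
rs6732518	2	60708597	C	T	BCL11A
rs10189857	2	60713235	A	G	BCL11A
rs6545816	2	60714861	A	C	BCL11A
rs7599488	2	60718347	C	T	BCL11A
rs1427407	2	60718043	T	G	BCL11A
rs766432	2	60719970	C	A	BCL11A
rs10184550	2	60729294	G	A	BCL11A
rs7606173	2	60725451	G	C	BCL11A
rs6706648	2	60722040	C	T	BCL11A
rs28384513	6	135376209	T	G	HBS1L-MYB
rs7776054	6	135418916	A	G	HBS1L-MYB
rs9399137	6	135419018	T	C	HBS1L-MYB
rs9389268	6	135419631	A	G	HBS1L-MYB
rs4895441	6	135426573	A	G	HBS1L-MYB
rs6929404	6	135454027	C	A	HBS1L-MYB
rs9402686	6	135427817	G	A	HBS1L-MYB
rs1320963	6	135443212	A	G	HBS1L-MYB
rs6904897	6	135382980	T	G	HBS1L-MYB
rs35959442	6	135424179	C	G	HBS1L-MYB
rs9376090	6	135411228	T	C	HBS1L-MYB
rs4895440	6	135426558	A	T	HBS1L-MYB
rs9494142	6	135431640	T	C	HBS1L-MYB
rs9402685	6	135419688	T	C	HBS1L-MYB
rs11759553	6	135422296	A	T	HBS1L-MYB
rs6934903	6	135451564	T	A	HBS1L-MYB
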