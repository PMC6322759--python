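case_id	sex	ga	gene	chrom	pos	ref	alt	hgvs_c	hgvs_p	consequence	zygosity	dbsnp	cadd_scaled	maf_exac_nfe	maf_swegen	reported_in_affected	functional_evidence	conservation_low	splice_prediction_affected	acmg_class_published
112	XX	32+3	ABCC9	chr12	22063090	C	T	c.1320+1G>A	-	splice_site	homozygous	rs139620148	27.6	0.000060	0.0015	0	0	0	1	3
286	XY	41+1	ANK2	chr4	114294462	C	T	c.11716C>T	p.(Arg3906Trp)	missense	heterozygous	rs121912706	35	0.001724	0.0030	1	1	0	0	3
82	XY	31+0	BAG3	chr10	121431911	C	T	c.652C>T	p.(Arg218Trp)	missense	heterozygous	rs397514506	32	0.000030	-	1	1	0	0	3
69	XX	39+4	CACNB2	chr10	18828181	C	T	c.1439C>T	p.(Thr480Ile)	missense	heterozygous	rs143326262	22.2	0.002388	-	1	0	0	0	3
34	XX	27+4	CSRP3	chr11	19207878	C	T	c.299G>A	p.(Arg100His)	missense	heterozygous	rs138218523	24.9	0.002008	0.0050	1	0	0	0	3
82	XY	31+0	DES	chr2	220285586	G	A	c.934G>A	p.(Asp312Asn)	missense	heterozygous	rs34337334	34	0.000015	-	1	1	0	0	3
217	XX	24+0	DSG2	chr18	29125783	G	A	c.2434G>A	p.(Gly812Ser)	missense	heterozygous	rs121913010	28.6	0.000030	-	1	1	0	0	3
250	XY	23+3	DSG2	chr18	29126689	C	T	c.3340C>T	p.(Gln1114*)	nonsense	heterozygous	-	42	-	-	0	0	0	0	4
101	XY	39+0	DSP	chr6	7580494	G	C	c.4071G>C	p.(Glu1357Asp)	missense	heterozygous	rs569786610	23.6	-	-	1	0	0	0	3
22	XX	40+3	DSP	chr6	7584376	C	G	c.6881C>G	p.(Ala2294Gly)	missense	heterozygous	rs147000526	28.8	0.000974	0.0005	1	0	0	0	3
149	XY	35+6	GPD1L	chr3	32181723	A	G	c.370A>G	p.(Ile124Val)	missense	heterozygous	rs72552293	3.81	0.002397	0.0040	1	1	0	0	3
164	XY	35+6	GPD1L	chr3	32181723	A	G	c.370A>G	p.(Ile124Val)	missense	heterozygous	rs72552293	3.81	0.002397	0.0040	1	1	0	0	3
238	XY	37+6	GPD1L	chr3	32181723	A	G	c.370A>G	p.(Ile124Val)	missense	heterozygous	rs72552293	3.81	0.002397	0.0040	1	1	0	0	3
273	XX	38+4	GPD1L	chr3	32181723	A	G	c.370A>G	p.(Ile124Val)	missense	heterozygous	rs72552293	3.81	0.002397	0.0040	1	1	0	0	3
290	XY	36+1	KCNH2	chr7	150645550	G	A	c.2674C>T	p.(Arg892Cys)	missense	heterozygous	rs201627778	32	0.000215	-	1	0	0	0	3
11	XY	23+0	KCNJ8	chr12	21918667	G	A	c.1265C>T	p.(Ser422Leu)	missense	heterozygous	rs72554071	16.5	0.002518	0.0005	1	1	0	0	3
5	XY	27+0	KCNQ1	chr11	2466656	G	A	c.328G>A	p.(Val110Ile)	missense	heterozygous	rs199472677	22.7	0.000145	-	1	1	0	0	3
228	XY	37+4	KCNQ1	chr11	2466656	G	A	c.328G>A	p.(Val110Ile)	missense	heterozygous	rs199472677	22.7	0.000145	-	1	1	0	0	3
63	XY	29+5	KCNQ1	chr11	2594115	A	G	c.820A>G	p.(Ile274Val)	missense	heterozygous	rs199472728	25.1	0.000365	0.0005	1	1	0	0	3
108	XX	27+4	KCNQ1	chr11	2608860	C	T	c.1189C>T	p.(Arg397Trp)	missense	heterozygous	rs199472776	33	0.000270	-	1	1	0	0	3
88	XY	Full term	KCNQ1	chr11	2610069	G	A	c.1378G>A	p.(Gly460Ser)	missense	heterozygous	rs199472783	10.07	0.000047	-	1	0	0	0	3
61	XY	26+0	MYBPC3	chr11	47359047	C	T	c.2497G>A	p.(Ala833Thr)	missense	heterozygous	rs199865688	32	0.002730	0.0030	1	0	0	0	3
202	XX	37+1	MYBPC3	chr11	47359047	C	T	c.2497G>A	p.(Ala833Thr)	missense	heterozygous	rs199865688	32	0.002730	0.0030	1	0	0	0	3
290	XY	36+1	MYH7	chr14	23894566	C	T	c.2348G>A	p.(Arg783His)	missense	heterozygous	rs397516142	25.2	0.000030	-	1	0	0	0	3
256	XX	36+4	NEBL	chr10	21157673	C	T	c.604G>A	p.(Gly202Arg)	missense	heterozygous	rs137973321	19.89	0.003120	0.0020	1	1	0	0	3
46	XY	29+0	NEXN	chr1	78395131	A	C	c.995A>C	p.(Glu332Ala)	missense	heterozygous	rs201763096	23.2	0.002821	0.0005	1	0	0	0	3
286	XY	25+2	PKP2	chr12	32949101	G	T	c.2431C>A	p.(Arg811Ser)	missense	heterozygous	rs139734328	34	0.001154	0.0015	1	0	0	0	3
150	XX	36+3	RYR2	chr1	237934127	G	A	c.11497G>A	p.(Asp3833Asn)	missense	heterozygous	-	25.2	0.000104	-	1	0	0	0	3
245	XX	34+5	RYR2	chr1	237774125	C	T	c.4747C>T	p.(Pro1583Ser)	missense	heterozygous	rs200070226	32	0.000131	-	1	0	0	0	3
4	XX	37+1	RYR2	chr1	237791277	G	A	c.6337G>A	p.(Val2113Met)	missense	heterozygous	rs186906598	19.5	0.000752	0.0015	1	0	0	0	3
209	XY	22+2	SCN5A	chr3	38645430	C	A	c.1663G>T	p.(Glu555*)	nonsense	heterozygous	-	24.2	-	-	0	0	0	0	4
55	XY	28+4	SCN5A	chr3	38645235	G	A	c.1858C>T	p.(Arg620Cys)	missense	heterozygous	rs199473577	25.1	-	-	1	0	0	0	3
177	XX	24+2	SCN5A	chr3	38592513	C	T	c.5350G>A	p.(Glu1784Lys)	missense	heterozygous	-	33	-	-	1	0	0	0	3
199	XY	25+3	TNNI3	chr19	55666189	G	A	c.292C>T	p.(Arg98*)	nonsense	heterozygous	-	40	0.000151	-	0	0	0	0	3
104	XY	30	TRPM4	chr19	49684650	CGCCTGGCC	C	c.1195_1202del	p.(Leu399Glyfs*11)	frameshift	heterozygous	-	34	0.000030	-	0	0	0	0	4
34	XX	27+4	TRPM4	chr19	49703651	A	T	c.2740A>T	p.(Lys914*)	nonsense	heterozygous	rs140799936	54	0.002213	0.0020	1	1	0	0	3
261	XY	27+4	TRPM4	chr19	49703651	A	T	c.2740A>T	p.(Lys914*)	nonsense	heterozygous	rs140799936	54	0.002213	0.0020	1	1	0	0	3
26	XY	24	TRPM4	chr19	49713558	T	C	c.3224T>C	p.(Leu1075Pro)	missense	heterozygous	rs144421653	28.5	0.000195	-	1	1	0	0	3
65	XY	37+4	TTN	chr2	179581821	C	A	c.25639+1G>T	-	splice_site	heterozygous	-	24.9	-	-	0	0	0	1	4
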