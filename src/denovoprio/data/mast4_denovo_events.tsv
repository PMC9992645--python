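Sample ID	gDNA change	Function	Coding change	Protein change	SIFT	Polyphen	CADD	MutationTaster	PROVEAN	M-CAP	VEST4	GERP	phyloP	ExAC	1000 genomes	gnomAD	Inheritance	PMID	Cohort Size	Primary diagnosis
95,715	g.66437967A > G	Missense	c.2519A > G	p.840H > R	D	D	25.5	D	D	D	0.944	5.42	1.312			0.0000112	De novo	33057194	31058	DD
Case 1	g.66438324T > C	Missense	c.2693T > C	p.898I > T	D	D	22.9	D	D	D	0.715	5.78	1.138				De novo	This study	Unknown	IS
DDD13k.08536	g.66440524C > T	Stop gain	c.2758C > T	p.920Q > X			38	A			0.36	5.16	1.026				De novo	33057194	31058	DD
DDD13k.00269	g.66459419C > T	Missense	c.4412C > T	p.1471T > I	D	P	26.3	D	D	D	0.719	5.4	1.026				De novo	33057194	31058	DD
Case 2	g.66459419C > T	Missense	c.4412C > T	p.1471T > I	D	P	26.3	D	D	D	0.719	5.4	1.026				De novo	This study	Unknown	IS
Case 3	g.66459419C > T	Missense	c.4412C > T	p.1471T > I	D	P	26.3	D	D	D	0.719	5.4	1.026				De novo	This study	Unknown	IS
18,847	g.66460439C > T	Missense	c.5432C > T	p.1811S > F	D	D	27.3	D	D	D	0.965	5.14	1.026				De novo	33057194	31058	DD
66,810	g.66460439C > T	Missense	c.5432C > T	p.1811S > F	D	D	27.3	D	D	D	0.965	5.14	1.026				De novo	33057194	31058	DD
Case 4	g.66462662C > G	Missense	c.7655C > G	p.2552S > W	D	D	23.4	D	N	D	0.512	5.06	0.08				De novo	This study	Unknown	IS
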