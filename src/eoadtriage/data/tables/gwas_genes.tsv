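gene	hgvs_c	hgvs_p	patient_id	fh_score	clinvar	hgmd	gnomad_nfe	conflicting_detail	zygosity	prediction	flags	app_exon
ADAM10	c.112A>G	p.Asn38Asp	AD#060	0	NR	NR	NR		het	likely_benign		.
ADAM10	c.556dupC	p.Gln186ProfsTer19	AD#065	3.5	NR	NR	NR		het	likely_pathogenic	PTV	.
BIN1	c.696C>A	p.Asn232Lys	AD#095	0	vus	NR	98/129022		het	.		.
BIN1	c.865G>A	p.Ala289Thr	AD#009	0	NR	NR	3/94156		het	likely_benign		.
BIN1	c.1462-3C>T	.	AD#082	0	vus	NR	16/128710		het	.		.
CLU	c.509C>T	p.Thr170Met	AD#096	0	NR	NR	2/113698		het	likely_benign		.
CR1	c.4956G>A	p.Pro1652=	AD#062	0	NR	NR	NR		het	likely_benign		.
CR1	c.4356T>C	p.Cys1452=	AD#075	0	NR	NR	1084/128002		het	likely_benign		.
ELAVL1	c.765C>T	p.Ala255=	AD#010	3.5	NR	NR	29/129192		het	likely_benign		.
EP300	c.2194C>T	p.Pro732Ser	AD#098	0	NR	NR	NR		het	likely_pathogenic		.
EPHA1	c.928A>G	p.Ile310Val	AD#010	3.5	NR	NR	1/113284		het	likely_benign		.
FERMT2	c.1077G>C	p.Gly359=	AD#028	3.5	NR	NR	1083/127414		het	likely_benign		.
FERMT2	c.1538C>T	p.Thr513Met	AD#058	0	NR	NR	487/129124		het	likely_pathogenic		.
			AD#060	0					het	.		.
INPP5D	c.470G>A	p.Arg157Gln	AD#090	0	NR	NR	300/127840		het	likely_pathogenic		.
INPP5D	c.2085C>T	p.Pro695=	AD#089	3.5	NR	NR	107/128314		het	likely_benign		.
MARK2	c.1611C>T	p.Ser537=	AD#090	0	NR	NR	5/108824		het	likely_benign		.
MARK4	c.1553C>T	p.Pro518Leu	AD#060	0	NR	NR	196/129058		het	likely_benign		.
PICALM	c.1231G>C	p.Ala411Pro	AD#014	0	NR	NR	321/128802		het	likely_pathogenic		.
PLCG2	c.3379C>A	p.Pro1127Thr	AD#032	3.5	NR	NR	3/128682		het	likely_pathogenic		.
PLCG2	c.408G>A	p.Ala136=	AD#083	0	NR	NR	1/128708		het	likely_benign		.
PTK2B	c.2591C>T	p.Ala864Val	AD#010	3.5	NR	Parkinson disease?	275/129154		het	.		.
RIN3	c.2377T>C	p.Tyr793His	AD#022	0	NR	NR	896/129136		het	likely_pathogenic		.
TOMM40	c.384C>G	p.Asn128Lys	AD#082	0	NR	NR	4/113466		het	likely_benign		.
ZCWPW1	c.1834C>T	p.Leu612=	AD#052	3.5	NR	NR	1126/128540		het	likely_benign		.
ZCWPW1	c.314A>G	p.Glu105Gly	AD#097	0	NR	NR	623/128268		het	likely_pathogenic		.
ZCWPW1	c.283-5T>G	.	AD#088	0	NR	NR	1072/128080		het	likely_benign		.
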