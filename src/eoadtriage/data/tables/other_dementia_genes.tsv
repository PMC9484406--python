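gene	hgvs_c	hgvs_p	patient_id	fh_score	clinvar	hgmd	gnomad_nfe	conflicting_detail	zygosity	prediction	flags	app_exon
CCNF	c.353T>C	p.Val118Ala	AD#020	0	NR	NR	1/111550		het	likely_pathogenic		.
CCNF	c.656T>C	p.Leu219Pro	AD#079	1.5	NR	NR	5/111832		het	likely_pathogenic		.
CHCHD10	c.354C>A	p.Asp118Glu	AD#068	0	vus	NR	NR		het	.		.
CSF1R	c.1400C>T	p.Thr467Met	AD#081	0	NR	NR	5/113734		het	likely_benign		.
CSF1R	c.1477A>G	p.Ser493Gly	AD#057	3.5	NR	NR	NR		het	likely_benign		.
CSF1R	c.2850C>A	p.His950Gln	AD#044	0	NR	NR	2/113066		het	likely_benign		.
CSF1R	c.2851C>A	p.Leu951Met	AD#044	0	NR	NR	2/113102		het	likely_benign		.
DCTN1	c.586A>G	p.Ile196Val	AD#102	3.5	conflicting	abnormal cellular organization	649/105456	VUS:2;B:6	het	.		.
DCTN1	c.1361T>C	p.Val454Ala	AD#030	0	NR	NR	NR		het	likely_pathogenic		.
DCTN1	c.1480G>A	p.Ala494Thr	AD#100	3	vus	amyotrophic lateral sclerosis, phenotype modifiers?	4/128890		het	.		.
DCTN1	c.1555A>G	p.Lys519Glu	AD#067	0	NR	NR	NR		het	likely_pathogenic		.
DCTN1	c.2278A>G	p.Met760Val	AD#070	1	conflicting	NR	10/129140	VUS:2;B:2;LB:1	het	.		.
DCTN1	c.2989C>T	p.Arg997Trp	AD#078	0	vus	amyotrophic lateral sclerosis	1/113370		het	.		.
FIG4	c.2200G>A	p.Glu734Lys	AD#080	0	vus	NR	15/113494		het	.		.
FIG4	c.2467C>T	p.Gln823Ter	AD#097	0	pathogenic	NR	7/129138		hom_alt	.		.
FUS	c.430_447del	p.Gly144_Tyr149del	AD#039	0	conflicting	NR	10/113750	P:1;LP:1;VUS:1	het	.		.
FUS	c.681_686del	p.Gly230_Gly231del	AD#033	1.5	conflicting	NR	56/117710	B:1;VUS:1	het	.		.
			AD#049	3.5					het	.		.
MAPT	c.121G>A	p.Ala41Thr	AD#039	0	vus	Alzheimer disease?	6/128512		het	.		.
MAPT	c.454G>A	p.Ala152Thr	AD#017	3.5	conflicting	neurodegeneration	297/129002	VUS:2;B:1;LB:2	het	.		.
NOTCH3	c.1505C>T	p.Ser502Phe	AD#085	0	vus	NR	9/75540		het	.		.
NOTCH3	c.3315C>T	p.Gly1105=	AD#071	3	NR	NR	1/113330		het	likely_benign		.
NOTCH3	c.3535A>G	p.Asn1179Asp	AD#099	0	NR	NR	NR		het	likely_pathogenic		.
NOTCH3	c.4461C>T	p.Gly1487=	AD#074	3.5	NR	NR	NR		het	likely_benign		.
NOTCH3	c.5816-6C>T	.	AD#093	3.5	NR	NR	6/113474		het	likely_benign		.
OPTN	c.448C>T	p.Leu150=	AD#010	3.5	NR	NR	7/129170		het	likely_benign		.
OPTN	c.941A>T	p.Gln314Leu	AD#091	3.5	conflicting	amyotrophic lateral sclerosis	38/129076	P:1;VUS:1	het	.		.
OPTN	c.1401+4A>G	.	AD#069	0	vus	amyotrophic lateral sclerosis	17/129180		het	.		.
OPTN	c.1643G>A	p.Arg548Gln	AD#053	0	vus	NR	9/129122		het	.		.
SQSTM1	c.315C>T	p.Cys105=	AD#066	0	NR	NR	NR		het	likely_benign		.
SQSTM1	c.960G>A	p.Gly320=	AD#092	3.5	NR	NR	1/81718		het	likely_benign		.
SQSTM1	c.1175C>T	p.Pro392Leu	AD#032	3.5	conflicting	paget disease of bone	173/128718	P:4;LP:1;VUS:2;B:1	het	.		.
TYROBP	c.140T>C	p.Val47Ala	AD#077	0	vus	Alzheimer disease, early onset?	14/128556		het	.		.
UBQLN2	c.1461C>A	p.Thr487=	AD#095	0	conflicting	NR	787/87391	VUS:1;B:5;LB:1	het	.		.
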