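gene	hgvs_c	hgvs_p	patient_id	fh_score	clinvar	hgmd	gnomad_nfe	conflicting_detail	zygosity	prediction	flags	app_exon
APP	c.1305C>T	p.Phe435=	AD#089	3.5	benign	NR	132/128888		het	.		.
APP	c.2137G>A	p.Ala713Thr	AD#101	3.5	conflicting	Alzheimer disease	4/129100	LP:1;VUS:2	het	.		17
APP	c.2229C>T	p.Thr743=	AD#010	3.5	NR	NR	NR		het	likely_benign		18
PSEN1	c.104G>A	p.Arg35Gln	AD#043	0	conflicting	Alzheimer disease?	37/129122	VUS:3;B:1;LB:1	het	.		.
PSEN1	c.253C>T	p.Leu85Phe	AD#102	3.5	NR	NR	NR		het	likely_pathogenic		.
PSEN1	c.275G>C	p.Cys92Ser	AD#055	1.5	pathogenic	Alzheimer disease	NR		het	.		.
PSEN1	c.497T>A	p.Leu166His	AD#001	3.5	NR	Alzheimer disease, early-onset	NR		het	.		.
PSEN1	c.617G>C	p.Gly206Ala	AD#057	3.5	pathogenic	Alzheimer disease	NR		het	.		.
PSEN1	c.791C>T	p.Pro264Leu	AD#012	1	pathogenic	Alzheimer disease	NR		het	.		.
PSEN1	c.1172T>C	p.Val391Ala	AD#002	3.5	NR	Alzheimer disease	NR		het	.		.
PSEN1	c.1315A>G	p.Ile439Val	AD#101	3.5	NR	Alzheimer disease	NR		het	.		.
PSEN1	c.185G>A	p.Arg62His	AD#022	0	benign	Alzheimer disease?	300/128852		het	.		.
PSEN2	c.211C>T	p.Arg71Trp	AD#097	0	benign	Alzheimer disease?	506/129030		het	.	QUESTIONABLE_PATHOGENICITY	.
			AD#098	0					het	.		.
			AD#077	0					het	.		.
PSEN2	c.520A>G	p.Met174Val	AD#035	3	benign	Alzheimer disease?	44/129182		het	.	QUESTIONABLE_PATHOGENICITY	.
			AD#091	3.5					het	.		.
PSEN2	c.668G>C	p.Gly223Ala	AD#043	0	NR	Alzheimer disease	NR		het	.		.
PSEN2	c.708T>C	p.Ser236=	AD#065	3.5	benign	NR	791/129088		het	.		.
PSEN2	c.1186C>T	p.Leu396Phe	AD#053	0	NR	Alzheimer disease	1/113608		het	.		.
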