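gene	hgvs_c	hgvs_p	patient_id	fh_score	clinvar	hgmd	gnomad_nfe	conflicting_detail	zygosity	prediction	flags	app_exon
ABCA7	c.2126_2132delAGCAGGG	p.Glu709AlafsTer86	AD#009	0	conflicting	NR	250/104264	VUS:1;LB:1	het	.	PTV,PRIOR_AD_REPORT	.
ABCA7	c.2476G>A	p.Gly826Arg	AD#052	3.5	NR	NR	95/126126		het	likely_pathogenic		.
ABCA7	c.2629G>A	p.Ala877Thr	AD#088	0	NR	NR	1014/127604		het	likely_benign		.
ABCA7	c.3412A>C	p.Ser1138Arg	AD#006	0	NR	NR	1/76428		het	likely_pathogenic		.
ABCA7	c.3472+5G>C	.	AD#009	0	NR	NR	2/112726		het	likely_benign	PRIOR_AD_REPORT	.
ABCA7	c.4343G>A	p.Gly1448Asp	AD#083	0	NR	NR	72/127544		het	likely_benign		.
ABCA7	c.4795G>A	p.Val1599Met	AD#007	0	likely_benign	autism?	554/129150		het	.		.
ABCA7	c.5570+5G>C	.	AD#028	3.5	vus	Alzheimer disease?	432/114436		het	.		.
			AD#099	0					het	.		.
SORL1	c.133G>T	p.Asp45Tyr	AD#094	3.5	NR	NR	4/39936		het	likely_pathogenic		.
SORL1	c.1805C>T	p.Ser602Leu	AD#052	3.5	NR	Alzheimer disease?	NR		het	.		.
SORL1	c.3346A>G	p.Ile1116Val	AD#096	0	benign	Alzheimer disease, late-onset?	1065/129098		het	.		.
SORL1	c.4077C>T	p.Cys1359=	AD#062	0	vus	NR	33/129196		het	.		.
SORL1	c.5448T>C	p.Tyr1816=	AD#097	0	benign	NR	285/128866		het	.		.
SORL1	c.6150A>G	p.Glu2050=	AD#088	0	NR	NR	1/113030		het	likely_benign		.
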