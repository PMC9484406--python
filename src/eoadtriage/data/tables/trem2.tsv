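gene	hgvs_c	hgvs_p	patient_id	fh_score	clinvar	hgmd	gnomad_nfe	conflicting_detail	zygosity	prediction	flags	app_exon
TREM2	c.140G>A	p.Arg47His	AD#085	0	likely_benign	Alzheimer disease, increased risk	315/127748		het	.		.
TREM2	c.287C>A	p.Thr96Lys	AD#026	3	benign	frontotemporal dementia, increased risk	130/129182		het	.		.
TREM2	c.632T>C	p.Leu211Pro	AD#026	3	benign	Alzheimer disease, increased risk	144/129164		het	.		.
TREM2	c.407G>A	p.Arg136Gln	AD#045	0	vus	Alzheimer disease?	17/128820		het	.		.
TREM2	c.668C>T	p.Thr223Ile	AD#089	3.5	benign	Alzheimer disease?	49/129176		het	.	QUESTIONABLE_PATHOGENICITY	.
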