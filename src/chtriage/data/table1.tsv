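patient	locus	genotype	type	gene	aa_change	vaf_pbc	vaf_tumor	vaf_plasma
C02	chr17:7577568	C/G	SNV	TP53	p.C238S	1.40	0.36	1.58
C08	chr17:7577535	C/A	SNV	TP53	p.R249M	0.11	N.D	0.13
C11	chr17:7577120	C/T	SNV	TP53	p.R273H	0.08	N.D	0.19
C12	chr20:57484420	C/T	SNV	GNAS	p.R201C	0.10	0.05	0.32
C14	chr17:7578536	T/G	SNV	TP53	p.K132Q	0.23	N.D	0.18
C23	chr17:7577094	G/A	SNV	TP53	p.R282W	0.08	0.11	0.20
C25	chr17:7578457	C/T	SNV	TP53	p.R158H	0.06	0.35	0.15
C26	chr17:7578263	G/A	SNV	TP53	p.R196*	0.37	N.D	0.28
C27	chr17:7577570	C/T	SNV	TP53	p.M237I	0.05	0.08	0.34
C37	chr17:7577121	G/A	SNV	TP53	p.R273C	0.08	0.38	0.35
C44	chr17:7578403	C/T	SNV	TP53	p.C176Y	0.06	0.22	0.10
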