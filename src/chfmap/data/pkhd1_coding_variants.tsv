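chromosome	position_bp	ref_allele	alt_allele	gene	cdna	protein	note
chr20	49398500	C	T	PKHD1	c.10796G>A	p.R3599H	.
chr20	49398692	A	C	PKHD1	c.10604T>G	p.L3535R	.
chr20	49597760	A	T	PKHD1	c.6845T>A	p.I2282N	.
chr20	49630834	G	A	PKHD1	c.6112C>T	p.H2038Y	.
chr20	49630951	T	C	PKHD1	c.5995A>G	p.K1999E	.
chr20	49709730	C	A	PKHD1	c.4462T>G	p.A1488S	.
chr20	49709928	C	T	PKHD1	c.4264G>A	p.D1422N	.
chr20	49710356	G	C	PKHD1	c.3836C>G	p.A1279G	.
chr20	49710359	C	T	PKHD1	c.3833G>A	p.R1278Q	.
chr20	49710363	A	G	PKHD1	c.3829T>C	p.S1277P	.
chr20	49710468	C	T	PKHD1	c.3724G>A	p.E1242K	.
chr20	49740355	C	T	PKHD1	c.1811G>A	p.R604Q	.
chr20	49741254	C	T	PKHD1	c.1670G>A	p.R557Q	.
chr20	49766468	T	C	PKHD1	c.317A>G	p.E106G	.
chr20	50077556	G	GC	EFHC1	.	.	assembly_error
chr20	50077559	G	GC	EFHC1	.	.	assembly_error
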