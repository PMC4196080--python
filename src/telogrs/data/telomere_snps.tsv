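rsid	chrom	pos	gene	effect_allele	other_allele	maf	weight	melanoma_beta	melanoma_p
rs10936599	3	169492101	TERC	T	C	0.252	-0.097	-0.079	0.0003
rs2736100	5	1286516	TERT	C	A	0.486	0.078	0.078	0.02
rs7675998	4	164007820	NAF1	A	G	0.217	-0.074	-0.063	0.03
rs9420907	10	105676465	OBFC1	C	A	0.135	0.069	0.083	0.001
rs8105767	19	22215441	ZNF208	G	A	0.291	0.048	0.028	0.16
rs755017	20	62421622	RTEL1	G	A	0.131	0.062	0.026	0.35
rs11125529	2	54475866	ACYP2	A	C	0.142	0.056	-0.004	0.86
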