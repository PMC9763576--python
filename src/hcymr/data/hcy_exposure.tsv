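rsid	gene	chrom	effect_allele	other_allele	eaf	beta	se	pvalue
rs1801133	MTHFR	1	A	NA	0.34	0.1583	0.007	4.34E-104
rs2275565	MTR	1	T	NA	0.21	-0.0542	0.009	1.96E-10
rs9369898	MUT	6	A	NA	0.62	0.0449	0.007	2.17E-10
rs7130284	NOX4	11	T	NA	0.07	-0.1242	0.013	1.88E-20
rs154657	DPEP1	16	A	NA	0.45	0.0963	0.007	1.74E-43
rs4660306	MMACHC	1	T	NA	0.33	0.0435	0.007	2.33E-09
rs548987	SLC17A3	6	C	NA	0.13	0.0597	0.01	1.12E-08
rs42648	GTPB10	7	A	NA	0.40	-0.0395	0.007	1.97E-08
rs1801222	CUBN	10	A	NA	0.34	0.0453	0.007	8.43E-10
rs2251468	HNF1A	12	A	NA	0.65	-0.0512	0.007	1.28E-12
rs838133	FUT2	19	A	NA	0.45	0.0422	0.007	7.48E-09
rs12780845	CUBN	10	A	NA	0.65	0.0529	0.009	7.80E-10
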