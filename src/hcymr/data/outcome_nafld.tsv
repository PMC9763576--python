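rsid	effect_allele	other_allele	beta	se
rs1801133	A	NA	0.063	0.042
rs2275565	T	NA	0.044	0.044
rs9369898	A	NA	-0.012	0.037
rs7130284	T	NA	-0.008	0.053
rs154657	A	NA	0.043	0.037
rs4660306	T	NA	0.000	0.038
rs548987	C	NA	0.014	0.063
rs42648	A	NA	-0.013	0.037
rs1801222	A	NA	0.049	0.038
rs2251468	A	NA	-0.047	0.037
rs838133	A	NA	0.013	0.037
rs12780845	A	NA	-0.081	0.041
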