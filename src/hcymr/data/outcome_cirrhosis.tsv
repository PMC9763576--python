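rsid	effect_allele	other_allele	beta	se
rs1801133	A	NA	-0.142	0.058
rs2275565	T	NA	-0.020	0.060
rs9369898	A	NA	0.052	0.050
rs7130284	T	NA	0.029	0.072
rs154657	A	NA	0.054	0.051
rs4660306	T	NA	0.102	0.052
rs548987	C	NA	-0.114	0.087
rs42648	A	NA	0.000	0.051
rs1801222	A	NA	-0.030	0.053
rs2251468	A	NA	0.026	0.050
rs838133	A	NA	0.025	0.051
rs12780845	A	NA	-0.021	0.057
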