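rsid	effect_allele	other_allele	beta	se
rs1801133	A	NA	-0.037	0.168
rs2275565	T	NA	-0.020	0.173
rs9369898	A	NA	0.297	0.146
rs7130284	T	NA	-0.244	0.210
rs154657	A	NA	0.144	0.147
rs4660306	T	NA	-0.036	0.150
rs548987	C	NA	-0.216	0.251
rs42648	A	NA	-0.069	0.147
rs1801222	A	NA	-0.057	0.153
rs2251468	A	NA	0.252	0.146
rs838133	A	NA	0.099	0.148
rs12780845	A	NA	0.236	0.165
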