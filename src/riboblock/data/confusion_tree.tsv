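predicted\true	Lysine	Cobalamin	Glycine	SAM-alpha	SAM-IV	Cyclic-di-GMP-I	SAH
Lysine	40	4	1	0	0	1	1
Cobalamin	11	402	8	1	7	1	0
Glycine	1	6	31	1	0	5	0
SAM-alpha	0	4	0	30	4	2	0
SAM-IV	1	0	1	1	34	3	0
Cyclic-di-GMP-I	1	7	2	1	11	131	2
SAH	1	1	0	1	5	3	41
TP	40	402	31	30	34	131	41
FP	15	22	12	5	27	15	44
TN	669	307	678	679	675	578	668
FN	7	28	13	10	6	24	52
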