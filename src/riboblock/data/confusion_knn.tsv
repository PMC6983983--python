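predicted\true	Lysine	Cobalamin	Glycine	SAM-alpha	SAM-IV	Cyclic-di-GMP-I	SAH
Lysine	39	3	2	0	0	2	1
Cobalamin	4	406	9	1	0	7	3
Glycine	0	14	28	0	0	2	0
SAM-alpha	0	5	1	32	0	1	1
SAM-IV	1	5	0	0	33	0	1
Cyclic-di-GMP-I	2	9	2	1	0	139	2
SAH	1	2	5	0	0	3	41
TP	39	406	28	32	33	139	41
FP	8	38	19	2	0	15	49
TN	679	312	690	686	685	579	677
FN	8	24	16	8	7	16	52
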