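predicted\true	Lysine	Cobalamin	Glycine	SAM-alpha	SAM-IV	Cyclic-di-GMP-I	SAH
Lysine	39	1	4	0	0	1	2
Cobalamin	6	407	7	3	1	5	1
Glycine	1	1	39	0	0	3	0
SAM-alpha	0	1	1	35	1	2	0
SAM-IV	0	1	0	1	37	1	0
Cyclic-di-GMP-I	1	2	7	2	0	141	2
SAH	0	0	2	0	0	2	48
TP	39	407	39	35	37	141	48
FP	8	6	21	6	2	14	53
TN	707	339	707	711	709	605	698
FN	8	23	5	5	3	14	52
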