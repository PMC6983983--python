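predicted\true	Lysine	Cobalamin	Glycine	SAM-alpha	SAM-IV	Cyclic-di-GMP-I	SAH
Lysine	33	1	10	3	0	0	0
Cobalamin	13	363	46	3	1	1	3
Glycine	0	0	44	0	0	0	0
SAM-alpha	0	0	4	36	0	0	0
SAM-IV	0	0	4	0	36	0	0
Cyclic-di-GMP-I	0	0	52	0	0	103	0
SAH	0	0	12	0	1	0	39
TP	33	363	44	36	36	103	39
FP	13	1	128	6	2	1	3
TN	621	291	610	618	618	551	615
FN	14	67	0	4	4	52	13
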