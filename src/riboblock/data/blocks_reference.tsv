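family	motif	location	prevalence
Lysine	AGAGGUGC	10	1.0
Lysine	AGUAA	28	1.0
Cobalamin	CGGUG	18	1.0
Cobalamin	GCA	77	1.0
Cobalamin	AGC	92	1.0
Cobalamin	AGA	175	1.0
Cobalamin	GACC	180	1.0
Glycine	GGAGA	13	1.0
Glycine	CCGA	35	1.0
SAM-alpha	GUGGU	11	1.0
SAM-alpha	AUUUG	17	1.0
SAM-alpha	GCCACGU	37	1.0
SAM-IV	UCA	3	1.0
SAM-IV	GAG	7	1.0
SAM-IV	CAG	13	1.0
SAM-IV	GCUGG	32	1.0
SAM-IV	CGGCAACC	38	1.0
Cyclic-di-GMP-I	GAAA	23	1.0
Cyclic-di-GMP-I	CGCAAAGC	35	1.0
SAH	GAGGAGCG	7	1.0
SAH	UGC	16	1.0
SAH	AGGCUCGG	36	1.0
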