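classifier	measure	class	expected_percent	strict
lda	accuracy	SAM-IV	99.09	1
lda	accuracy	Glycine	83.63	1
lda	sensitivity	Glycine	100	1
lda	sensitivity	Cyclic-di-GMP-I	66.45	1
lda	specificity	Cyclic-di-GMP-I	99.82	1
lda	specificity	Glycine	82.66	1
lda	f_score	SAM-IV	92.31	1
lda	f_score	Glycine	40.74	1
lda	accuracy	macro	93.98	0
lda	sensitivity	macro	82.3	1
lda	specificity	macro	96.9	1
lda	f_score	macro	77.97	1
lda	ccr	-	80.94	1
pnn	accuracy	SAM-IV	99.33	1
pnn	accuracy	SAH	87.66	1
pnn	sensitivity	Cobalamin	94.65	1
pnn	sensitivity	SAH	48	1
pnn	specificity	SAM-IV	99.72	1
pnn	specificity	SAH	92.94	1
pnn	f_score	Cobalamin	96.56	1
pnn	f_score	SAH	47.76	1
pnn	accuracy	macro	96.1	1
pnn	sensitivity	macro	83.61	0
pnn	specificity	macro	97.69	1
pnn	f_score	macro	81.91	1
pnn	ccr	-	92.31	0
tree	accuracy	SAM-alpha	97.93	1
tree	accuracy	SAH	88.07	1
tree	sensitivity	Cobalamin	93.49	1
tree	sensitivity	SAH	44.09	1
tree	specificity	SAM-alpha	99.27	1
tree	specificity	Cobalamin	93.31	1
tree	f_score	Cobalamin	94.15	1
tree	f_score	SAH	46.07	1
tree	accuracy	macro	94.79	0
tree	sensitivity	macro	76.81	1
tree	specificity	macro	96.58	1
tree	f_score	macro	74.9	1
tree	ccr	-	89.37	0
knn	accuracy	SAM-IV	99.03	1
knn	accuracy	SAH	87.67	1
knn	sensitivity	Cobalamin	94.42	1
knn	sensitivity	SAH	44.09	1
knn	specificity	SAM-IV	100	1
knn	specificity	Cobalamin	89.14	1
knn	f_score	Cobalamin	92.91	1
knn	f_score	SAH	44.81	1
knn	accuracy	macro	95.2	1
knn	sensitivity	macro	76.76	1
knn	specificity	macro	96.53	1
knn	f_score	macro	78.44	1
knn	ccr	-	88.86	1
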