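model	source_model	expression_threshold	method	TP	FP	FN	TN
iHeart1709	maximal	0.5	FBA	9	1	53	119
iHeart1696	maximal	0.7	FBA	9	1	53	119
iHeart1653	maximal	0.9	FBA	13	2	49	118
min-iHeart1716	minimal	0.5	FBA	9	1	53	119
min-iHeart1703	minimal	0.7	FBA	9	1	53	119
min-iHeart1651	minimal	0.9	FBA	13	1	49	119
iHeart1041	legacy	0.5	FBA	9	5	40	68
iHeart1034	legacy	0.7	FBA	9	5	40	68
iHeart983	legacy	0.9	FBA	9	5	40	68
iHeart1709	maximal	0.5	lMOMA	10	1	52	119
iHeart1696	maximal	0.7	lMOMA	10	1	52	119
iHeart1653	maximal	0.9	lMOMA	14	2	48	118
min-iHeart1716	minimal	0.5	lMOMA	10	1	52	119
min-iHeart1703	minimal	0.7	lMOMA	10	1	52	119
min-iHeart1651	minimal	0.9	lMOMA	14	1	48	119
iHeart1041	legacy	0.5	lMOMA	9	5	40	68
iHeart1034	legacy	0.7	lMOMA	9	5	40	68
iHeart983	legacy	0.9	lMOMA	9	5	40	68
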