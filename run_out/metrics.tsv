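fold	accuracy	precision	recall	f1	auc_roc	tp	tn	fp	fn
0	0.84	0.8235294117647058	0.9333333333333333	0.8749999999999999	0.94	14	7	3	1
1	0.88	1.0	0.8	0.888888888888889	0.98	12	10	0	3
2	0.84	0.7894736842105263	1.0	0.8823529411764706	0.8866666666666667	15	6	4	0
pooled	0.8533333333333334	0.8541666666666666	0.9111111111111111	0.8817204301075269	0.9288888888888889	41	23	7	4
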