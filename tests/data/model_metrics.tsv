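model	acc	sn	ppv	fscore	auc	average_performance
SVM	0.809	0.889	0.793	0.838	0.880	0.842
KNN	0.805	0.873	0.797	0.833	0.890	0.840
DT	0.805	0.838	0.817	0.827	0.900	0.837
LR	0.795	0.831	0.807	0.819	0.870	0.824
DA	0.793	0.836	0.801	0.818	0.870	0.824
NB	0.798	0.828	0.812	0.820	0.890	0.830
EL	0.817	0.890	0.803	0.844	0.910	0.853
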