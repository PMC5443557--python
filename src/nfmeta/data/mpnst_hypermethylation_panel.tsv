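gene_id	symbol	chromosome	band	score_mpnst_vs_nf	logfc_mpnst_vs_nf	score_mpnst_vs_control	logfc_mpnst_vs_control	meth_logfc_mpnst_vs_nf	meth_adj_p_mpnst_vs_nf	meth_logfc_mpnst_vs_control	meth_adj_p_mpnst_vs_control
ENSG00000068028	RASSF1	3	p21.31	-0.09	-0.70	0	-1.07	2.77	1.30e-02	3.35	1.64e-03
ENSG00000159200	RCAN1	21	q22.12	-0.64	-2.08	0	-1.11	2.41	1.28e-02	2.99	1.88e-07
ENSG00000197971	MBP	18	q23	-0.69	-2.96	-1.54	-7.13	3.41	1.06e-53	3.80	6.60e-59
ENSG00000175785	PRIMA1	14	q32.12	-0.71	-2.43	-0.67	-2.40	2.87	4.01e-05	3.09	5.52e-07
ENSG00000152061	RAGAP1L	1	q25.1	-0.73	-1.54	-0.24	-1.94	2.24	1.74e-05	2.55	5.11e-06
ENSG00000213088	ACKR1	1	q23.2	-1.00	-2.84	-0.78	-3.15	3.33	1.04e-02	2.03	2.30e-04
ENSG00000158887	MPZ	1	q23.3	-1.11	-2.49	-1.01	-5.09	2.27	3.46e-03	4.37	1.95e-08
ENSG00000070731	ST6GALNAC2	17	q25.1	-1.56	-2.81	-0.69	-2.93	2.01	1.31e-02	2.74	4.47e-06
ENSG00000132470	ITGB4	17	q25.1	-1.62	-3.13	-0.55	-2.29	1.90	6.70e-05	2.16	4.77e-02
ENSG00000160307	S100B	21	q22.3	-3.22	-4.31	-1.06	-4.94	2.56	2.02e-02	2.37	6.82e-04
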