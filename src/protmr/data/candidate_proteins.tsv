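tissue	protein_id	method	n_snps	or_	ci_low	ci_high	pvalue	fdr_q	cochran_q_p	egger_intercept_p	steiger_p	steiger_direction	pph4_pct	colocalized	causal_evidence
brain	GLRX5	ivw_fixed	4	0.84	0.78	0.90	8.83E-07	0.001	0.930	0.705	1.00E-400	correct	88.14	Yes	Yes
brain	GMPPB	ivw_fixed	2	1.64	1.33	2.03	5.68E-06	0.002	0.517	NA	1.06E-34	correct	75.45	Yes	Yes
brain	B3GALTL	ivw_fixed	2	0.79	0.70	0.89	7.16E-05	0.015	0.856	NA	2.46E-62	correct	24.04	No	No
brain	FUCA2	wald_ratio	1	0.80	0.72	0.90	1.25E-04	0.021	NA	NA	1.11E-18	correct	88.70	Yes	Yes
brain	TTLL12	ivw_fixed	2	0.67	0.54	0.83	2.71E-04	0.031	0.747	NA	6.60E-38	correct	14.85	No	No
brain	ADCK1	ivw_fixed	4	0.81	0.72	0.91	2.91E-04	0.032	0.750	0.531	5.00E-99	correct	2.64	No	No
brain	MMAA	ivw_fixed	2	0.77	0.66	0.89	4.38E-04	0.037	0.294	NA	2.59E-50	correct	19.27	No	No
brain	HIBADH	ivw_fixed	3	0.67	0.53	0.84	4.50E-04	0.037	0.136	0.419	1.65E-54	correct	1.38	No	No
brain	ACP1	ivw_fixed	4	1.19	1.08	1.32	5.21E-04	0.039	0.329	0.464	2.72E-301	correct	5.58	No	No
brain	DOC2A	wald_ratio	1	0.44	0.28	0.71	7.24E-04	0.048	NA	NA	9.45E-10	correct	61.22	No	No
blood	PEAR1	ivw_fixed	2	0.81	0.74	0.89	1.56E-05	0.019	0.327	NA	5.28E-112	correct	42.44	No	No
blood	NDE1	wald_ratio	1	1.74	1.29	2.34	2.59E-04	0.113	NA	NA	1.00E-09	correct	30.71	No	No
blood	EVA1C	wald_ratio	1	0.60	0.46	0.80	4.01E-04	0.126	NA	NA	4.69E-11	correct	57.82	No	No
blood	B4GALT2	ivw_fixed	3	0.87	0.80	0.94	4.12E-04	0.127	0.661	0.692	3.87E-118	correct	27.43	No	No
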