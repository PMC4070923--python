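# Per-gene degenerate-site statistics for 13 mitochondrial protein-coding
# genes across 10 tephritid species (B. minax HM776033, B. oleae AY210702,
# B. tryoni HQ130030, B. philippinensis DQ995281, B. carambolae EF014414,
# B. papayae DQ917578, B. dorsalis DQ845759, C. capitata AJ242872,
# B. correcta JX456552, B. cucurbitae JN635562).
# AT_*F: mean A+T percentage at 0/2/4-fold degenerate sites (+/- SD over species).
# subst_*F: nucleotide substitution frequency (substitutions per site of the class).
# R_0F_all, R_4F_all: class substitution count / substitution count at all degenerate sites.
# ASD: overall mean Poisson-corrected amino-acid distance among the species.
gene	AT_0F	sd_0F	subst_0F	AT_2F	sd_2F	subst_2F	AT_4F	sd_4F	subst_4F	R_0F_all	R_4F_all	ASD
nad2	70.96	1.41	0.198	74.61	8.66	0.811	74.33	10.99	1.689	0.290	0.362	0.117
cox1	56.53	0.21	0.025	73.31	8.55	0.743	84.93	7.82	1.409	0.046	0.606	0.014
cox2	59.71	0.74	0.074	76.92	7.67	0.624	82.47	8.64	1.306	0.148	0.514	0.036
atp8	68.92	0.81	0.235	81.54	8.66	0.577	83.33	11.86	1.400	0.400	0.350	0.164
atp6	68.76	2.92	0.459	63.36	2.91	0.227	62.46	6.84	0.590	0.780	0.141	0.280
cox3	57.46	0.36	0.034	75.10	5.61	0.655	87.34	4.95	1.266	0.068	0.552	0.014
nad3	68.38	1.05	0.192	76.61	10.74	0.831	82.12	8.50	1.485	0.300	0.350	0.105
nad6	72.59	1.44	0.265	80.12	8.60	0.655	87.68	4.11	1.326	0.417	0.297	0.168
cob	61.62	0.42	0.057	68.66	9.26	0.741	81.14	6.72	1.417	0.106	0.497	0.029
nad1	65.54	0.53	0.094	88.33	2.51	0.381	73.72	1.09	1.090	0.222	0.449	0.052
nad4l	71.44	1.44	0.107	87.94	4.12	0.397	83.46	8.32	1.154	0.244	0.385	0.053
nad4	76.42	3.72	0.783	77.49	1.86	0.172	41.72	0.73	0.004	0.936	0.004	0.382
nad5	66.33	1.23	0.172	85.77	4.83	0.313	85.18	5.45	1.234	0.357	0.431	0.083
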