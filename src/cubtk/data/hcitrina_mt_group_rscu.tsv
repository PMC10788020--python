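amino_acid	codon	rscu_high	rscu_low	delta_rscu	optimal_published
Ala	GCA	1.14	0.84	0.31	1
Ala	GCC	1.43	0.84	0.59	1
Ala	GCG	0.00	0.47	-0.47	0
Ala	GCU	1.43	1.86	-0.43	0
Cys	UGC	0.00	0.71	-0.71	0
Cys	UGU	2.00	1.29	0.71	1
Asp	GAC	0.44	0.90	-0.46	0
Asp	GAU	1.56	1.10	0.46	1
Glu	GAA	1.68	1.44	0.24	1
Glu	GAG	0.32	0.56	-0.24	0
Phe	UUC	0.48	0.97	-0.48	0
Phe	UUU	1.52	1.03	0.48	1
Gly	GGA	1.48	1.08	0.40	1
Gly	GGC	0.15	0.61	-0.46	0
Gly	GGG	0.30	1.22	-0.92	0
Gly	GGU	2.07	1.08	0.99	1
His	CAC	0.36	0.63	-0.26	0
His	CAU	1.64	1.38	0.26	1
Ile	AUA	0.30	1.12	-0.82	0
Ile	AUC	0.98	0.85	0.13	0
Ile	AUU	1.73	1.04	0.69	1
Lys	AAA	1.13	0.95	0.17	1
Lys	AAG	0.88	1.05	-0.17	0
Leu	CUA	0.68	0.83	-0.15	0
Leu	CUC	0.41	0.71	-0.30	0
Leu	CUG	0.14	0.53	-0.40	0
Leu	CUU	1.23	1.13	0.10	1
Leu	UUA	2.05	1.60	0.44	1
Leu	UUG	1.50	1.19	0.31	1
Asn	AAC	0.89	0.54	0.35	0
Asn	AAU	1.11	1.46	-0.35	0
Pro	CCA	0.84	1.33	-0.49	0
Pro	CCC	0.95	1.00	-0.05	0
Pro	CCG	0.95	0.83	0.11	0
Pro	CCU	1.26	0.83	0.43	1
Gln	CAA	1.63	1.50	0.13	1
Gln	CAG	0.38	0.50	-0.13	0
Arg	AGA	0.60	1.35	-0.75	0
Arg	AGG	0.60	1.01	-0.41	0
Arg	CGA	1.60	1.08	0.52	1
Arg	CGC	0.40	0.94	-0.54	0
Arg	CGG	1.00	0.74	0.26	0
Arg	CGU	1.80	0.88	0.92	1
Ser	AGC	0.35	0.59	-0.24	0
Ser	AGU	1.06	1.12	-0.06	0
Ser	UCA	0.94	0.99	-0.05	0
Ser	UCC	1.18	1.12	0.06	0
Ser	UCG	1.29	0.66	0.63	1
Ser	UCU	1.18	1.52	-0.34	0
Thr	ACA	1.00	1.10	-0.10	0
Thr	ACC	1.00	1.10	-0.10	0
Thr	ACG	0.60	0.94	-0.34	0
Thr	ACU	1.40	0.86	0.54	1
Val	GUA	0.95	1.17	-0.22	0
Val	GUC	0.76	1.11	-0.35	0
Val	GUG	0.19	0.92	-0.73	0
Val	GUU	2.10	0.80	1.30	1
Tyr	UAC	0.13	0.64	-0.51	0
Tyr	UAU	1.87	1.36	0.51	1
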