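gene	codon_counts	gc1	gc2	gc3	gcall	cai	cbi	fop	enc
atp1	510	57.45	42.55	34.90	44.97	0.17	-0.10	0.35	52.75
atp4	195	44.62	43.08	37.95	41.88	0.16	-0.08	0.36	59.92
atp6	248	44.76	37.90	31.85	38.17	0.15	-0.18	0.29	50.34
atp8	281	45.20	33.45	43.42	40.69	0.17	0.01	0.41	58.37
ccmB	207	45.41	43.48	34.30	41.06	0.17	-0.07	0.35	44.91
ccmC	273	47.25	48.35	35.90	43.83	0.17	-0.01	0.39	49.88
ccmFc	449	48.78	44.77	42.32	45.29	0.14	-0.10	0.35	57.34
ccmFn	614	50.16	48.86	42.02	47.01	0.16	-0.05	0.38	57.28
cob	390	50.26	41.54	34.62	42.14	0.16	-0.12	0.32	56.44
cox1	528	48.30	45.45	36.74	43.50	0.19	-0.03	0.39	53.89
cox2	273	52.01	39.56	33.33	41.64	0.20	-0.07	0.36	49.39
cox3	266	52.26	45.11	35.34	44.24	0.20	-0.04	0.38	56.00
matR	673	53.94	43.39	56.76	51.36	0.15	0.02	0.42	57.49
nad2	182	40.66	38.46	36.81	38.64	0.16	-0.16	0.30	54.26
nad3	119	44.54	46.22	36.97	42.58	0.19	-0.11	0.33	48.69
nad4	496	46.57	43.95	36.69	42.41	0.16	-0.06	0.36	52.72
nad5	482	44.40	46.06	38.38	42.95	0.17	-0.11	0.35	56.49
nad6	232	46.55	41.81	44.40	44.25	0.14	-0.04	0.36	58.91
nad7	395	56.46	46.08	30.89	44.47	0.17	-0.05	0.36	49.56
nad9	191	51.83	42.41	32.46	42.23	0.21	-0.06	0.39	54.87
rpl5	196	49.49	36.22	41.84	42.52	0.17	-0.09	0.37	56.43
rps1	167	47.90	38.92	41.92	42.91	0.18	-0.10	0.35	49.21
rps2	232	42.67	40.95	36.21	39.94	0.17	-0.12	0.35	55.45
rps3	562	44.31	40.21	43.77	42.76	0.15	-0.07	0.38	60.01
rps4	345	41.74	40.58	38.55	40.29	0.12	-0.03	0.39	55.18
rps12	126	56.35	47.62	30.16	44.71	0.15	-0.02	0.40	55.71
rps13	117	50.43	40.17	29.91	40.17	0.16	-0.12	0.35	39.34
rps14	101	42.57	46.53	36.63	41.91	0.16	-0.08	0.35	51.37
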