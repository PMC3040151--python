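candidate	gene_id	locus	primer	conc_f	conc_m	mf_ratio	t	p_value
ENSTGUG00000000043	ENSTGUG00000000043	exon3	1	0.47	0.95	2.03	5.48	0.00077
ENSTGUG00000000043	ENSTGUG00000000043	exon4	2	0.70	1.69	2.40	4.14	0.00305
ENSTGUG00000000468	ENSTGUG00000000468	exon4	1	0.45	0.80	1.79	5.37	0.00085
ENSTGUG00000000468	ENSTGUG00000000468	3'UTR	2	0.28	0.57	2.02	6.60	0.00029
ENSTGUG00000000630	ENSTGUG00000000630	exon4	1	0.48	0.96	1.97	10.99	0.00002
ENSTGUG00000000903	ENSTGUG00000000903	3'UTR	1	0.22	0.46	2.10	4.51	0.00203
ENSTGUG00000000903	ENSTGUG00000000903	exon26	2	0.44	0.86	1.94	5.49	0.00077
ENSTGUG00000001006	ENSTGUG00000001006	exon4	1	0.31	0.59	1.92	6.62	0.00029
ENSTGUG00000001006	ENSTGUG00000001006	3'UTR	2	0.50	1.00	2.03	17.43	0.00000
ENSTGUG00000001006.b	ENSTGUG00000001006	exon1	1	0.30	0.66	2.20	5.58	0.00071
ENSTGUG00000001019	ENSTGUG00000001019	exon4	1	0.34	0.64	1.90	8.37	0.00008
ENSTGUG00000001019	ENSTGUG00000001019	exon5	2	0.48	0.96	1.98	8.73	0.00006
ENSTGUG00000001401	ENSTGUG00000001401	3'UTR	1	0.50	1.00	1.99	4.71	0.00164
ENSTGUG00000001401	ENSTGUG00000001401	3'UTR	2	0.23	0.48	2.09	10.07	0.00003
ENSTGUG00000001582	ENSTGUG00000001582	exon5	1	0.30	0.66	2.20	9.70	0.00003
ENSTGUG00000001587	ENSTGUG00000001587	3'UTR	1	0.26	0.56	2.17	5.66	0.00065
ENSTGUG00000001918	ENSTGUG00000001918	3'UTR	1	0.40	0.78	1.95	5.34	0.00088
ENSTGUG00000001918	ENSTGUG00000001918	3'UTR	2	0.39	0.79	2.04	7.83	0.00011
ENSTGUG00000001918	ENSTGUG00000001918	3'UTR	3	0.49	1.03	2.11	6.62	0.00029
ENSTGUG00000002186	ENSTGUG00000002186	exon2	1	0.26	0.64	2.45	30.20	0.00000
ENSTGUG00000002186	ENSTGUG00000002186	exon2	2	0.29	0.67	2.32	8.24	0.00009
ENSTGUG00000002229	ENSTGUG00000002229	3'UTR	1	0.48	1.00	2.09	4.55	0.00195
ENSTGUG00000002229	ENSTGUG00000002229	exon5	2	0.33	0.69	2.07	4.04	0.00339
ENSTGUG00000003373	ENSTGUG00000003373	exon5	1	0.38	0.77	2.05	13.08	0.00001
ENSTGUG00000003968	ENSTGUG00000003968	exon3	1	0.42	0.93	2.21	7.34	0.00016
ENSTGUG00000004334	ENSTGUG00000004334	exon4	1	0.42	0.92	2.18	7.60	0.00014
ENSTGUG00000006083	ENSTGUG00000006083	exon5	1	0.39	0.84	2.15	9.66	0.00004
ENSTGUG00000006814	ENSTGUG00000006814	exon2	1	0.44	0.90	2.03	4.82	0.00148
ENSTGUG00000006923	ENSTGUG00000006923	exon4	1	0.51	1.05	2.06	11.07	0.00002
ENSTGUG00000017495	ENSTGUG00000017495	exon12	1	0.73	0.83	1.14	1.17	0.14404
ENSTGUG00000017495	ENSTGUG00000017495	exon13	2	1.51	1.60	1.06	0.65	0.26995
ENSTGUG00000017495	ENSTGUG00000017495	exon17	3	1.75	1.85	1.05	0.41	0.34855
ENSTGUG00000017495	ENSTGUG00000017495	3'UTR	4	2.21	2.35	1.07	0.53	0.30709
ENSTGUG00000017495	ENSTGUG00000017495	3'UTR	5	0.68	0.76	1.12	0.72	0.24832
ENSTGUG00000017495	ENSTGUG00000017495	exon9	6	1.70	1.80	1.06	0.50	0.31822
ENSTGUG00000017541	ENSTGUG00000017541	3'UTR	1	0.40	0.88	2.21	6.98	0.00021
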