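region	chromosome	start_mb	end_mb	top_snp	maf	bf	allele_substitution_effect	pct_genetic_variance	n_genes
1	2	32.99	34.51	ALGA0012906	0.27	66.7	-0.143	0.17	1
2	2	140.44	140.93	ISU10000081	0.28	22.7	-0.17	0.11	12
3	3	39.13	39.28	MARC0000538	0.35	15.4	-0.079	0.04	1
4	3	44.55	45.82	ASGA0014296	0.29	16.4	-0.067	0.06	22
5	3	113.1	113.41	ALGA0020641	0.3	16.4	-0.068	0.08	1
6	3	134.97	135.69	ASGA0090006	0.23	35.5	-0.051	0.23	12
7	3	138.21	138.59	ALGA0115665	0.18	17.5	-0.117	0.07	0
8	4	139.72	140.10	H3GA0014860	0.39	15.4	-0.002	0.04	3
9	7	55.41	58.19	H3GA0021793	0.35	31.2	0.187	0.57	28
10	7	63.59	63.78	DRGA0007689	0.46	17.5	0.151	0.05	4
11	7	73.7	74.94	DRGA0007771	0.32	10.2	-0.155	0.04	1
12	7	87.05	91.15	ALGA0042950	0.35	28	0.157	0.29	7
13	7	102.01	105.22	ALGA0122954	0.21	210.1	0.227	2.5	156
14	8	33.26	35.00	ASGA0093882	0.34	44.3	0.16	0.38	11
15	8	43.92	45.19	ALGA0119079	0.23	22.7	-0.205	0.06	12
16	8	55.18	58.63	ALGA0047889	0.18	23.8	-0.198	0.24	26
17	8	80.00	81.42	MARC0044036	0.18	25.9	0.246	0.12	8
18	8	130.69	130.91	ALGA0049466	0.46	37.7	0.054	0.2	1
19	8	143.24	143.35	ALGA0050050	0.36	17.5	-0.073	0.05	1
20	9	36.15	38.36	UMB10000133	0.18	97.5	-0.158	0.24	20
21	9	75.48	76.83	ALGA0053672	0.39	20.6	-0.171	0.16	2
22	9	85.48	85.84	H3GA0027836	0.29	16.4	-0.17	0.07	2
23	10	52.21	53.94	DRGA0010548	0.09	122.3	0.39	0.29	10
24	10	56.37	56.78	ASGA0103067	0.48	35.5	0.101	0.09	2
25	11	25.34	26.23	ALGA0061540	0.3	19.5	0.171	0.05	7
26	12	42.93	44.76	ALGA0123748	0.25	18.5	-0.141	0.14	18
27	12	48.73	49.13	ASGA0082658	0.24	16.4	0.234	0.06	4
28	12	51.95	52.62	ALGA0066876	0.47	156.4	0.094	1.1	4
29	12	54.70	56.06	H3GA0034702	0.19	78.4	0.212	0.29	90
30	14	80.44	84.34	ALGA0079106	0.48	140.4	0.143	0.56	47
31	15	3.02	3.24	H3GA0043638	0.07	17.5	0.309	0.03	1
32	15	8.04	8.91	ASGA0068444	0.26	30.1	0.195	0.06	3
33	15	26.16	26.82	CASI0009989	0.17	16.4	0.235	0.05	1
34	15	147.34	147.74	ASGA0071500	0.25	17.5	0.246	0.04	8
35	15	153.82	154.57	M1GA0027067	0.4	53.1	-0.027	0.35	23
36	16	1.02	1.03	H3GA0045756	0.44	12.3	-0.034	0.04	0
37	16	27.60	30.67	DRGA0016028	0.34	30.1	0.035	0.43	24
38	18	21.22	21.27	H3GA0050517	0.47	13.3	-0.228	0.05	0
39	18	50.12	51.64	ASGA0080142	0.21	15.4	0.237	0.06	6
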