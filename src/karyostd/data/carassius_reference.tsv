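chromosome	CAU_median_i	CCA_median_i	CGI_median_i	CAU_category	CCA_category	CGI_category
1	47.87	48.28	48.55	m	m	m
2	47.07	45.68	46.12	m	m	m
3	45.74	44.74	44.99	m	m	m
4	44.81	43.52	43.47	m	m	m
5	43.46	42.11	42.53	m	m	m
6	42.43	41.08	40.89	m	m	m
7	41.63	39.58	39.89	m	m	m
8	40.84	37.90	38.42	m	m	m
9	40.13	36.81	36.91	m	sm	sm
10	39.67	36.17	35.84	m	sm	sm
11	38.75	35.79	35.41	m	sm	sm
12	37.65	35.19	34.73	m	sm	sm
13	36.77	34.86	34.25	sm	sm	sm
14	36.19	34.36	33.36	sm	sm	sm
15	35.88	33.66	32.61	sm	sm	sm
16	35.71	32.70	31.90	sm	sm	sm
17	35.48	32.22	28.62	sm	sm	sm
18	35.21	31.23	26.86	sm	sm	sm
19	34.87	30.54	26.07	sm	sm	sm
20	34.33	29.11	24.42	sm	sm	st
21	33.45	28.54	23.45	sm	sm	st
22	33.03	27.41	22.83	sm	sm	st
23	32.78	26.86	21.37	sm	sm	st
24	31.95	26.25	16.52	sm	sm	st
25	31.41	25.22	9.19	sm	sm	a
26	31.08	24.00	0.00	sm	st	T
27	30.70	22.57	0.00	sm	st	T
28	30.11	20.62	0.00	sm	st	T
29	29.75	18.13	0.00	sm	st	T
30	28.96	0.00	0.00	sm	T	T
31	28.17	0.00	0.00	sm	T	T
32	26.87	0.00	0.00	sm	T	T
33	24.41	0.00	0.00	st	T	T
34	11.19	0.00	0.00	a	T	T
35	0.00	0.00	0.00	T	T	T
36	0.00	0.00	0.00	T	T	T
37	0.00	0.00	0.00	T	T	T
38	0.00	0.00	0.00	T	T	T
39	0.00	0.00	0.00	T	T	T
40	0.00	0.00	0.00	T	T	T
41	0.00	0.00	0.00	T	T	T
42	0.00	0.00	0.00	T	T	T
43	0.00	0.00	0.00	T	T	T
44	0.00	0.00	0.00	T	T	T
45	0.00	0.00	0.00	T	T	T
46	0.00	0.00	0.00	T	T	T
47	0.00	0.00	0.00	T	T	T
48	0.00	0.00	0.00	T	T	T
49	0.00	0.00	0.00	T	T	T
50	0.00	0.00	0.00	T	T	T
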