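locus	Na	Ne	I	Obs_Ho	Obs_He	Exp_Ho	Exp_He	H	PIC_pct
Tea_ILP1116	6.00	3.89	1.53	1.00	0.00	0.26	0.74	0.74	70.71
Tea_ILP1418	4.00	2.13	0.83	0.01	0.99	0.47	0.53	0.53	41.91
Tea_ILP1396	4.00	2.16	0.92	0.81	0.19	0.46	0.54	0.54	46.58
Tea_ILP1000	5.00	3.29	1.31	1.00	0.00	0.30	0.70	0.70	63.95
Tea_ILP1589	3.00	1.87	0.71	0.34	0.66	0.53	0.47	0.46	37.12
Tea_ILP900	2.00	1.32	0.41	0.72	0.28	0.76	0.24	0.24	21.40
Tea_ILP1097	2.00	1.97	0.69	1.00	0.00	0.51	0.49	0.49	37.11
Tea_ILP1023	6.00	3.54	1.42	0.95	0.05	0.28	0.72	0.72	66.92
Tea_ILP1222	3.00	1.76	0.77	0.76	0.24	0.57	0.43	0.43	39.22
Tea_ILP1192	4.00	1.59	0.73	0.80	0.20	0.63	0.37	0.37	34.69
Tea_ILP1073	3.00	1.26	0.39	0.80	0.20	0.80	0.20	0.20	18.71
Tea_ILP591	7.00	5.00	1.72	1.00	0.00	0.20	0.80	0.80	77.16
Tea_ILP1158	4.00	3.86	1.37	0.47	0.53	0.26	0.74	0.74	69.26
Tea_ILP072	2.00	1.62	0.57	0.48	0.52	0.62	0.38	0.38	30.99
Tea_ILP015	4.00	3.07	1.16	1.00	0.00	0.32	0.68	0.67	60.45
Tea_ILP290	2.00	1.78	0.63	1.00	0.00	0.56	0.44	0.44	34.21
Tea_ILP380	5.00	3.74	1.40	0.53	0.47	0.27	0.74	0.73	68.66
Tea_ILP450	3.00	1.52	0.57	0.59	0.41	0.66	0.34	0.34	29.16
Tea_ILP202	3.00	2.48	0.98	1.00	0.00	0.40	0.60	0.60	51.77
Tea_ILP284	4.00	2.68	1.07	1.00	0.00	0.37	0.63	0.63	55.01
Tea_ILP1875	8.00	6.07	1.92	1.00	0.00	0.16	0.84	0.84	81.51
Tea_ILP1946	4.00	3.14	1.20	1.00	0.00	0.32	0.68	0.68	61.60
Tea_ILP1986	10.00	7.63	2.11	1.00	0.00	0.13	0.87	0.87	85.48
Tea_ILP2114	7.00	3.01	1.32	1.00	0.00	0.33	0.67	0.67	61.18
Tea_ILP2142	4.00	1.31	0.49	0.97	0.03	0.77	0.24	0.23	21.94
Tea_ILP2171	5.00	2.67	1.24	1.00	0.00	0.37	0.63	0.63	58.70
Tea_ILP1923	3.00	2.08	0.78	0.10	0.90	0.48	0.52	0.52	40.57
Tea_ILP1924	5.00	1.35	0.60	1.00	0.00	0.74	0.26	0.26	25.02
Tea_ILP1945	4.00	2.11	0.86	0.26	0.74	0.47	0.53	0.53	43.27
Tea_ILP1951	3.00	1.78	0.76	0.56	0.44	0.56	0.44	0.44	38.52
Tea_ILP1967	4.00	3.11	1.18	1.00	0.00	0.32	0.68	0.68	61.01
Tea_ILP1982	5.00	1.46	0.66	1.00	0.00	0.68	0.32	0.32	29.83
Tea_ILP1991	4.00	1.85	0.75	0.40	0.60	0.54	0.46	0.46	37.74
Tea_ILP2017	6.00	2.83	1.34	1.00	0.00	0.35	0.65	0.65	61.13
Tea_ILP2551	2.00	1.54	0.54	0.55	0.45	0.65	0.35	0.35	28.96
Tea_ILP3195	5.00	2.71	1.15	1.00	0.00	0.37	0.63	0.63	55.95
Tea_ILP1959	3.00	2.00	0.74	0.15	0.85	0.50	0.50	0.50	38.65
Tea_ILP3087	3.00	1.15	0.27	0.88	0.13	0.87	0.13	0.13	12.10
Tea_ILP1953	4.00	2.97	1.13	1.00	0.00	0.34	0.66	0.66	59.18
Tea_ILP2343	4.00	2.02	0.92	1.00	0.00	0.49	0.51	0.50	45.10
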