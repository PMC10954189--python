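methbin	chr	pos	avg	median	avg_male	avg_female	pvalue	MF_avg	MF_runavg	FHM_blockid
chrZ_30195000	Z	30195000	80.17	70.52	71.05	91.62	0.0141	0.78	1.26	1
chrZ_30196000	Z	30196000	52.73	48.01	42.69	65.32	2.07e-05	0.65	1.25	1
chrZ_30197000	Z	30197000	78.65	73.65	70.17	89.28	0.00732	0.79	1.23	1
chrZ_30198000	Z	30198000	66.48	60.78	56.4	79.13	0.000262	0.71	1.2	1
chrZ_30199000	Z	30199000	69.29	61.94	61.36	79.25	0.0164	0.77	1.18	1
chrZ_30200000	Z	30200000	32.7	30.17	28.75	37.65	0.0192	0.76	1.16	1
chrZ_42633000	Z	42633000	57.33	50.01	49.31	67.39	0.00438	0.73	1.53	2
chrZ_42634000	Z	42634000	81.07	76.75	67.55	98.04	1.25e-05	0.69	1.5	2
chrZ_42635000	Z	42635000	64.55	59.29	54.35	77.36	0.000173	0.7	1.46	2
chrZ_42636000	Z	42636000	64.06	59.41	55.99	74.2	0.00446	0.75	1.43	2
chrZ_42637000	Z	42637000	87.94	82.79	77.66	100.85	0.00171	0.77	1.43	2
chrZ_42638000	Z	42638000	77.38	73.39	69.06	87.82	0.0281	0.79	1.42	2
chrZ_49068000	Z	49068000	33.32	33.1	29.34	38.32	0.000941	0.77	1.43	3
chrZ_49069000	Z	49069000	103.06	93.79	88.37	121.5	0.000215	0.73	1.41	3
chrZ_49070000	Z	49070000	73.53	64.76	61.14	89.06	0.000155	0.69	1.38	3
chrZ_49071000	Z	49071000	82.15	76.27	69.69	97.78	0.00024	0.71	1.34	3
chrZ_49072000	Z	49072000	109.91	100.09	91.25	133.31	1.73e-06	0.68	1.31	3
chrZ_49073000	Z	49073000	51.46	46.02	42.84	62.27	0.000495	0.69	1.27	3
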