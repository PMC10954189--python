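id	num_qtl	marker	chr	pos	CI_low_marker	CI_high_marker	CI_low_pos	CI_high_pos	CI_size	num_genes
hotspot_1	11	Gg_rs14793763	1	13847380	Gg_rs13832402	Gg_rs15194859	12488579	14847187	2358608	50
hotspot_2	23	Gg_rs14858437	1	92741754	Gg_rs13901810	Gg_rs13910957	91200315	101131756	9931441	129
hotspot_3	11	Gg_rs15060526	2	8387159	Gg_rs14132382	Gg_rs14139143	5843745	11697701	5853956	87
hotspot_4	64	Gg_rs15282380	3	17984384	X3_16300000	Gg_rs14327472	15489694	23999342	8509648	201
hotspot_5	16	Gg_rs15416272	3	86515515	Gg_rs15403420	Gg_rs15427786	79192646	91808917	12616271	177
hotspot_6	19	X4_1267185	4	1286191	X4_1267185	Gg_rs13546113	1286191	1841819	555628	39
hotspot_7	14	Gg_rs15679503	5	22362570	snp.98.79.91070.S.2	Gg_rs15685956	17614557	25665093	8050536	184
hotspot_8	27	Gg_rs14568888	6	7742744	Gg_rs15765462	Gg_rs15777012	6568227	10633493	4065266	72
hotspot_9	11	Gg_rs15828492	7	2469584	Gg_rs15826188	Gg_rs16575534	1680380	3673817	1993437	26
hotspot_10	18	Gg_rs13609494	12	5538321	Gg_rs13621493	Gg_rs14974529	3076405	6304262	3227857	92
hotspot_11	37	rbl1871	14	15000631	Gg_rs15002638	rbl1871	13628710	15000631	1371921	52
hotspot_12	12	Gg_rs13744918	17	3944254	Gg_rs15033588	Gg_rs13744523	2473253	5465495	2992242	76
hotspot_13	39	GG_rs16782623	Z	41699011	Gg_rs16768340	Gg_rs16114279	37374725	52128174	14753449	176
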