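chrom	n_snps	length_mb	n_genes	snp_per_100kb	genes_per_100kb	r2_value
A01	5756	23.27	3448	25	15	0.053
A02	6854	24.79	3491	28	14	0.091
A03	7188	29.77	5476	24	18	0.064
A04	5261	19.15	2721	27	14	0.069
A05	7008	23.07	3418	30	15	0.060
A06	6804	24.40	3741	28	15	0.116
A07	6411	24.01	3593	27	15	0.068
A08	4474	18.96	2914	24	15	0.096
A09	8199	33.87	5157	24	15	0.092
A10	5352	17.40	2772	31	16	0.070
C01	9407	38.83	4064	24	10	0.282
C02	9248	46.22	4411	20	10	0.221
C03	11515	60.57	7113	19	12	0.093
C04	11316	48.93	5171	23	11	0.240
C05	6968	43.19	4895	16	11	0.083
C06	7134	37.23	4072	19	11	0.113
C07	9900	44.77	4772	22	11	0.252
C08	8231	38.48	4614	21	12	0.154
C09	6295	48.51	5084	13	10	0.119
A genome	63307	238.69	36731	27	15	0.078
C genome	80014	406.73	44196	20	11	0.173
AC genome	143321	645.42	80927	22	13	0.123
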