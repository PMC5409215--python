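chrom	chrom_length_bp	n_blocks	block_length_bp	frequency_pct
A01	23267856	1077	1822637	7.83
A02	24793737	1240	2603566	10.50
A03	29767490	1418	2825900	9.49
A04	19151660	987	1649516	8.61
A05	23067598	1314	2443836	10.59
A06	24396386	1320	2780562	11.40
A07	24006521	1236	2122650	8.84
A08	18961941	848	2060175	10.86
A09	33865340	1592	3234961	9.55
A10	17398227	1053	2626566	15.10
C01	38829317	1474	8763513	22.57
C02	46221804	1564	7396336	16.00
C03	60573394	2050	7064423	11.66
C04	48930237	1875	8356263	17.08
C05	43185227	1136	3374479	7.81
C06	37225952	1199	4665746	12.53
C07	44770477	1627	6404941	14.31
C08	38477087	1323	7312052	19.00
C09	48508220	1133	3336424	6.88
Total	645398471	25466	80844546	12.53
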