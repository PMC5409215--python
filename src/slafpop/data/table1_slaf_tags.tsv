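chrom	chrom_length_bp	expected_slaf	avg_distance_bp	n_slaf	polymorphic_slaf
A01	52457410	12193	4302	13001	6561
A02	53983291	12551	4301	13899	7531
A03	58957044	13716	4298	15795	8593
A04	48341214	11029	4383	9726	5708
A05	52257152	12446	4199	11781	7051
A06	53585940	12458	4301	13546	7659
A07	53196075	12566	4233	12608	7061
A08	48151495	11184	4305	10103	5236
A09	63054894	14577	4326	18278	9444
A10	46587781	11118	4190	9764	5898
C01	68018871	15840	4294	22280	10283
C02	75411359	17873	4219	24171	11034
C03	89762950	21336	4207	34884	15699
C04	78119791	18607	4198	28008	11987
C05	72374781	17061	4242	27328	8098
C06	66415506	15664	4240	21720	9119
C07	73960031	17332	4267	27003	11161
C08	67666641	15658	4322	24253	10660
C09	77697774	18009	4314	29670	9544
Total	1200000000	281218	4267	161262	70384
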