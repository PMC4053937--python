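tissue_or_stress	code	raw_abundance	raw_distinct	genome_matched_abundance	genome_matched_distinct
Root	BDI08	5103699	1055138	3942845	597486
Seedling	OBD03	2624702	1263576	1566530	548313
Leaf 1	BDI04	5207568	1425013	4305921	959519
Leaf 2	BDI09	6991777	736393	5315520	270687
Stem	BDI06	3855537	1926121	3209322	1435137
Leaf and stem	OBD02	3603581	1633352	2316244	739198
Panicle 1	BDI05	4944182	2166081	4102150	1567160
Panicle 2	OBD01	3992373	2135020	2783725	1191806
Shoot control for stress	BDI02	2494849	1077185	1975853	800615
Drought-stressed shoot	BDI03	1351288	515704	1038168	351245
Salt-stressed shoot	BDI17	8498042	2149559	7275111	1542354
Cold-stressed shoot	BDI01	722947	379189	538881	260131
Heat-stressed shoot	BDI18	8861608	2936249	7336506	2042837
Submergence-stressed shoot	BDI19	9421125	4336814	7586861	3037780
Shoot control for low phosphate	BDI15	11491988	2924520	9510554	2086843
Phosphate-starved shoot	BDI16	12405206	2977218	10490572	2153426
Pooled stresses	OBD04	2531278	1133267	1753994	590660
Total		94101750	21441607	75048757	12108240
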