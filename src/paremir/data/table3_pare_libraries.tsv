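tissue	code	trimmed_total	trimmed_distinct	genome_matched_total	genome_matched_distinct	cdna_matched_total	cdna_matched_distinct	cdna_loci
Root	BDI20	10748481	2342429	9279374	1605048	4298418	1021275	22762
Leaf	BDI21	13772836	1238807	12266285	684817	4930319	391613	20333
Stem	BDI23	16367640	3847003	12740059	1422289	5534630	656849	24168
Panicle	BDI25	29050139	4820607	26566704	3419993	15078495	2203450	20538
Total		69939096		60852422	5202600	29841862	3165429	25129
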