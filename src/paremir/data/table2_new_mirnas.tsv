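family	name	sequence	length	abundance
5163	Bdi-miR5163b-3p	UAGAUAUUUCAGGUUGUGUGGA	22	36348
5181	Bdi-miR5181e	CGACACUUACUGUGGCUCGGA	21	277
5185	Bdi-miR5185l-3p.2	UGGAGAUUGACUUAGAAGCGG	21	360
7731	Bdi-miR7731	AACAAGGGAUGCACAUACUUUGAG	24	836
7738	Bdi-miR7738-3p	GUGCUUGACAGACGACUCUGG	21	446
7754	Bdi-miR7754-3p	UUCUCUCGGCUAAGGAACUGC	21	392
9480	Bdi-miR9480ab	UAUGUGAGGGUGGUAACUGAA	21	1645
9481	Bdi-miR9481a	UCAGUCGGAUUUCUCACCUUCGAA	24	384
9481	Bdi-miR9481b	UCAGUCGGAUUUCUCACCUUC	21	73
9482	Bdi-miR9482	CCUUUGGGGAAGAAGGGAAAC	21	339
9483	Bdi-miR9483ab	UUGAACUGUUUCCUCUGAAGUUCC	24	317
9484	Bdi-miR9484	UAGUGCAGGGAGAAGUCGGUC	21	259
9485	Bdi-miR9485	UUAUGACGUGUAGGAGUUGCA	21	260
9486	Bdi-miR9486a	AUGCUUUCAAGGGAUUAGAGGUUC	24	254
9486	Bdi-miR9486a.2	UCUAAUGGCUGAAAUGGGAAG	21	183
9486	Bdi-miR9486b	UAAGUGAUUAGAGGUUCCAGU	21	121
9487	Bdi-miR9487	CCUUGUUCGAUUGCAAGAUGA	21	174
9488	Bdi-miR9488	UGAGGGCUAGGCUUUUAUGUAA	22	161
9489	Bdi-miR9489	UCAGCUCCACGGACUUGGUGA	21	144
9490	Bdi-miR9490	AGGCCACACCCUAAUGGUCGUGCG	24	111
9491	Bdi-miR9491	UGGUAUGUUACCUCUGAUCAG	21	69
9492	Bdi-miR9492	UAUCUACUCUGUCAUGGUAUC	21	60
9493	Bdi-miR9493	AAGAAUUAUGAAACGAAGGGAGUA	24	60
9494	Bdi-miR9494	UUCAUCACCUUCGUCUCCGUC	21	56
9495	Bdi-miR9495	UGAAAAAUGCCUCUGGACGUG	21	55
9496	Bdi-miR9496	CUGGUUGGGCUUAGAUGGGUCC	22	44
9497	Bdi-miR9497	UUUCUGAAUACAUGGUGUAUC	21	35
9498	Bdi-miR9498	GACCGUCAAGUGGUUGUUGAG	21	23
9499	Bdi-miR9499	CCCUCGUCGACGCGGCAGCUC	21	86
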