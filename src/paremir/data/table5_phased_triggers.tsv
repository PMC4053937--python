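mirna	phased_loci
miR390	2
miR2118a/b	288
miR2275	146
Bdi-miR5163b-3p	1
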