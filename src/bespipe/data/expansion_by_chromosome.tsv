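# Published expanded/contracted syntenic-region sums for the 42 concordant
# clones: sum of sugarcane BAC insert bp vs. the matching sorghum span bp,
# per sorghum chromosome and direction.
chrom	direction	n_regions	sugarcane_bp	sorghum_bp
chr01	expanded	2	228757	438099
chr01	contracted	2	246930	170629
chr02	expanded	7	843489	1530484
chr02	contracted	3	390747	307693
chr03	expanded	3	300722	649695
chr03	contracted	5	623310	501139
chr04	expanded	2	228311	542706
chr04	contracted	1	129840	60597
chr05	expanded	1	105911	192480
chr05	contracted	1	188640	93686
chr06	expanded	0	0	0
chr06	contracted	2	247660	68939
chr07	expanded	1	44210	296520
chr07	contracted	0	0	0
chr08	expanded	2	266020	341742
chr08	contracted	1	125996	124114
chr09	expanded	2	221580	423004
chr09	contracted	1	114955	91453
chr10	expanded	2	184310	374313
chr10	contracted	4	502882	283520
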