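# Published per-class clone counts for the 192 sampled BACs aligned against
# the 10 sorghum chromosomes.  aligned_bes is the number of end sequences of
# each clone that found a placement (2, 1 or 0).
class	aligned_bes	chromosome	orientation	distance_kb	verdict	bac_count
C1	2	same	opposite_in	20-300	concordant	42
C2	2	same	same	20-300	discordant	1
C3	2	same	opposite_in	>300	discordant	16
C4	2	same	same	>300	discordant	12
C5	2	same	opposite_out	>300	discordant	15
C6	2	different	na	na	discordant	9
C7	1	na	na	na	single_hit	10
C8	1	na	na	na	multi_hit	65
C9	0	na	na	na	no_hit	22
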