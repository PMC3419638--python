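# Published summary statistics of the SS_SBa sugarcane (SP80-3280) BAC library.
key	value
n_clones	36864
n_384well_plates	96
n_sampled_clones	192
mean_insert_kb	125
min_insert_kb	29
max_insert_kb	293
n_high_quality_bes	378
mean_read_length_bp	944
min_read_length_bp	312
chloroplast_contaminated_clones	1
monoploid_genome_size_min_mb	760
monoploid_genome_size_max_mb	930
revised_monoploid_genome_size_mb	580
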