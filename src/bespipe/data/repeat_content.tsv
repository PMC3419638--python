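# Published repeat-content ledger over the 378 high-quality BES reads:
# element counts and masked base totals per taxonomy node.  Internal nodes
# aggregate their children plus members identified only at that level, so
# children need not sum exactly to the parent.
label	n_elements	length_bp	pct_of_total_bases
Transposable Element	293	160624	44.29
RNA transposon	234	142693	39.35
LTR Retrotransposon	221	136899	37.76
Copia	96	65873	18.17
Gypsy	123	70697	19.50
Non-LTR Retrotransposon	13	5794	1.59
L1	7	2626	0.72
RTE	4	2943	0.81
SINE	2	225	0.06
SINE2/tRNA	2	225	0.06
DNA transposon	59	17931	4.94
EnSpm	13	5358	1.48
Harbinger	11	2728	0.75
Helitron	2	1197	0.33
MuDr	6	2515	0.69
hAT	9	3111	0.86
Integrated Virus	2	1231	0.34
Caulimoviridae	2	1231	0.34
Simple Repeat	3	1923	0.53
Satellite	3	1923	0.53
Total	298	163778	45.16
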