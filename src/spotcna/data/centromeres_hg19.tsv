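chromosome	position
chr1	125000000
chr2	93300000
chr3	91000000
chr4	50400000
chr5	48400000
chr6	61000000
chr7	59900000
chr8	45600000
chr9	49000000
chr10	40200000
chr11	53700000
chr12	35800000
chr13	17900000
chr14	17600000
chr15	19000000
chr16	36600000
chr17	24000000
chr18	17200000
chr19	26500000
chr20	27500000
chr21	13200000
chr22	14700000
chrX	60600000
chrY	12500000
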