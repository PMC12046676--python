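chromosome	position
chr1	123400000
chr2	93900000
chr3	90900000
chr4	50000000
chr5	48800000
chr6	59800000
chr7	60100000
chr8	45200000
chr9	43000000
chr10	39800000
chr11	53400000
chr12	35500000
chr13	17700000
chr14	17200000
chr15	19000000
chr16	36800000
chr17	25100000
chr18	18500000
chr19	26200000
chr20	28100000
chr21	12000000
chr22	15000000
chrX	61000000
chrY	10400000
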