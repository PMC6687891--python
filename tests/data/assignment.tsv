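tag	variants	n_reads	disqualified
AAAAACCCCCGGGGG	.	5	.
ACGTACGTACGTACG	3:T>A	5	.
TTTTTGGGGGCCCCC	7:G>-	5	.
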