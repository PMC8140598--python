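category	order	superfamily	count
retrotransposon	Non-LTR	LINEs	767
retrotransposon	Non-LTR	SINEs	551
retrotransposon	PLEs	Penelope	297
retrotransposon	DIRS	DIRS	356
retrotransposon	DIRS	VIPER	1
retrotransposon	DIRS	Ngaro	2
retrotransposon	Unclassified	Unclassified	1039
dna_transposon	TIR	Tc1-Mariner	2326
dna_transposon	TIR	hAT	2587
dna_transposon	TIR	Merlin	65
dna_transposon	TIR	Transib	119
dna_transposon	TIR	PiggyBac	19
dna_transposon	TIR	PIF-Harbinger	973
dna_transposon	TIR	MuDR	1016
dna_transposon	TIR	CACTA	57
dna_transposon	TIR	En-Spm	1265
dna_transposon	TIR	MITE	2312
dna_transposon	Crypton	Crypton	231
dna_transposon	Helitron	Helitron	740
dna_transposon	Unclassified	Unclassified	22354
non_te	-	RNA	262925
non_te	-	CDS	2713028
non_te	-	Chimeric	3566
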