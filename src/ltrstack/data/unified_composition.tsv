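class_code	superfamily	lineage	count
0	-	Other genomic features	34823
1	Copia	ALE/Retrofit	12031
3	Copia	Angela	1458
4	Copia	Bianca	1827
8	Copia	Ikeros	84
9	Copia	Ivana/Oryco	3556
12	Copia	Tork/Tar	6180
13	Copia	SIRE	3130
14	Gypsy	CRM	2136
16	Gypsy	Galadriel	549
17	Gypsy	Reina	4532
18	Gypsy	Tekay/DEL	10396
19	Gypsy	Athila	3499
20	Gypsy	TAT	17927
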