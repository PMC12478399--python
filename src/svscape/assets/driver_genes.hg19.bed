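# Selected pediatric-cancer driver genes, hg19 (0-based half-open BED).
# Used by the genic annotation stage; extend with a full gene model for
# production runs.
chr13	48877910	49056122	RB1
chr13	48892575	49032693	RCBTB2_flank
chr9	21967750	21995300	CDKN2A
chr12	11802787	12048325	ETV6
chr9	36833271	37034103	PAX5
chr21	36160097	36421595	RUNX1
chr11	118307204	118397539	KMT2A
chr22	29663997	29696515	EWSR1
chr11	32409320	32457081	WT1
chr17	7565096	7590856	TP53
chrX	76760355	77041755	ATRX
chrX	123094474	123236505	STAG2
chr17	29421944	29709134	NF1
chr19	1609289	1652615	TCF3
chr1	47681961	47698007	TAL1
chr1	47715810	47779819	STIL
chr12	12867992	12875305	CDKN1B
chr12	92537880	92539679	BTG1
chr4	108745710	109090112	LEF1
chrX	44732756	44971845	KDM6A
chrX	1314889	1331616	CRLF2
chr16	15737155	16421481	MYH11
chr8	128747680	128753674	MYC
chr8	130361775	131044592	CCDC26
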