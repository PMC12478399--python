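# Common fragile site (CFS) genes, hg19 (0-based half-open BED).  Large
# genes prone to breakage under replication stress; frequent passenger SV
# targets.  Coordinates are gene spans from standard annotation.
chr7	145813452	148118090	CNTNAP2
chr11	83166055	85338966	DLG2
chrX	31137344	33229673	DMD
chr9	8314245	10612723	PTPRD
chr7	69063904	70257885	AUTS2
chr20	13976145	16033842	MACROD2
chr3	60967685	62547686	FHIT
chr16	78133310	79246564	WWOX
chr6	161768589	162727802	PRKN
chr10	52750910	53818869	PRKG1
chr7	1855430	2272582	MAD1L1
chr7	3341079	4308632	SDK1
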