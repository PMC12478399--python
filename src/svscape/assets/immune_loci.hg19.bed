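# Antigen-receptor loci and representative orphan receptor regions, hg19
# (0-based half-open BED).  Curated from standard genome annotation; edit
# to taste -- the immune classification rule reads whatever is listed here.
chr14	106032613	107288051	IGH
chr2	89156873	90274235	IGK
chr22	22380473	23265085	IGL
chr14	22090056	23021075	TRA
chr7	141998850	142510972	TRB
chr14	22891536	22935569	TRD
chr7	38279624	38407656	TRG
chr15	21710826	22193837	IGH-O
chr16	32069197	33847733	IGH-O
chr2	114056935	114340016	IGK-O
chr22	20700820	20721369	IGL-O
chr9	33618000	33662000	TRB-O
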