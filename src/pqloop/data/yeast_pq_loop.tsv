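uniprot_id	swissprot_id	protein_name	gene_name	length	short_half_flag
Q12010	YO092_YEAST	Uncharacterized membrane protein YOL092W	YOL092W	308	false
Q03193	YD090_YEAST	Uncharacterized membrane protein YDR090C	YDR090C	310	false
P38279	RTC2_YEAST	Restriction of telomere capping protein 2	RTC2 YBR147W	296	false
P17261	ERS1_YEAST	Cystine transporter (ERD suppressor)	ERS1 YCR075C	260	false
Q06328	YD352_YEAST	Vacuolar integral membrane protein YDR352W	YDR352W	317	false
P18414	ERD2_YEAST	ER lumen protein retaining receptor (HDEL receptor)	ERD2 YBL040C	219	false
P25565	YCA2_YEAST	Putative uncharacterized protein YCL002C	YCL002C YCL2C	251	false
Q03687	YMP0_YEAST	Uncharacterized membrane protein YMR010W	YMR010W	405	false
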