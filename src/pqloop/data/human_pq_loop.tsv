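uniprot_id	swissprot_id	protein_name	gene_name	length	short_half_flag
P24390	ERD21_HUMAN	ER lumen protein retaining receptor 1 (KDEL receptor 1)	KDELR1	212	false
P33947	ERD22_HUMAN	ER lumen protein retaining receptor 2 (KDEL receptor 2)	KDELR2	212	false
O43731	ERD23_HUMAN	ER lumen protein retaining receptor 3 (KDEL receptor 3)	KDELR3	214	false
O60931	CTNS_HUMAN	Cystinosin	CTNS	367	false
O75352	MPU1_HUMAN	Mannose-P-dolichol utilization defect 1 protein	MPDU1	247	false
Q9BRV3	SWET1_HUMAN	Sugar transporter SWEET1, RAG1-activating protein 1 (Stromal cell protein)	SLC50A1 RAG1AP1	221	false
O96005	CLPT1_HUMAN	Cleft lip and palate transmembrane protein 1	CLPTM1	669	false
Q96KA5	CLP1L_HUMAN	Cleft lip and palate transmembrane protein 1-like protein (Cisplatin resistance-related protein 9)	CLPTM1L	538	false
Q2T9K0	TMM44_HUMAN	Transmembrane protein 44	TMEM44	475	false
Q8N2U9	PQLC1_HUMAN	PQ-loop repeat-containing protein 1	PQLC1	271	false
Q6ZP29	PQLC2_HUMAN	PQ-loop repeat-containing protein 2	PQLC2	291	false
Q8N755	PQLC3_HUMAN	PQ-loop repeat-containing protein 3	PQLC3	202	false
O95563	BR44_HUMAN	Brain protein 44 protein	BRP44	127	true
Q9Y5U8	BR44L_HUMAN	Brain protein 44-like protein	BRP44L	109	true
A1A4F0	CC055_HUMAN	Putative uncharacterized protein C3orf55	C3orf55	135	true
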