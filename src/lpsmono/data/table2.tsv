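Ensembl ID	HUGO geneID	Full name	foldchange	p-value
ENSG00000168383	HLA-DPB1	HLA class II histocompatibility antigen, DP(W4) beta chain precursor	0,44	4,2E-05
ENSG00000152518	ZFP36L2	Butyrate response factor 2	0,47	6,7E-05
ENSG00000158050	DUSP2	Dual specificity phosphatase 2	0,47	9,3E-04
ENSG00000148218	ALAD	Delta-aminolevulinic acid dehydratase	2,04	8,2E-04
ENSG00000152684	PELO	Pelota homolog	2,08	6,0 E-04
ENSG00000163220	S100A9	Calgranulin B	2,09	3,8 E-03
ENSG00000088986	DNCL1	Dynein light chain 1, cytoplasmic	2,15	8,2 E-04
ENSG00000134802	SLC43A3	Solute carrier family 43, member 3	2,17	3,1 E-03
ENSG00000163754	GYG	Glycogenin-1	2,21	1,1 E-03
ENSG00000084733	RAB10	Ras-related protein Rab-10	2,23	9,0 E-04
ENSG00000137312	FLOT1	Flotillin-1	2,23	2,6 E-03
ENSG00000023330	ALAS1	5-aminolevulinate synthase, nonspecific, mitochondrial precursor	2,24	1,6 E-03
ENSG00000015475	BID	BH3 interacting domain death agonist	2,27	2,6 E-03
ENSG00000123405	NFE2	Transcription factor NF-E2 45 kDa subunit	2,27	2,9 E-03
ENSG00000096238	CLIC1	Chloride intracellular channel protein 1	2,29	4,8 E-04
ENSG00000168439	STIP1	Stress-induced-phosphoprotein 1	2,29	3,1 E-03
ENSG00000101310	SEC23B	Protein transport protein Sec23B	2,32	6,0 E-04
ENSG00000106211	HSPB1	Heat-shock protein beta-1	2,33	2,1 E-03
ENSG00000102265	TIMP1	Metalloproteinase inhibitor 1 precursor	2,33	3,1 E-03
ENSG00000170458	CD14	Monocyte differentiation antigen CD14 precursor	2,40	4,8 E-04
ENSG00000155926	SLA	SRC-like-adapter	2,41	1,9 E-04
ENSG00000109971	HSPA8	Heat shock cognate 70 kDa protein	2,45	4,6 E-04
ENSG00000038427	VCAN	Versican core protein precursor	2,45	8,5 E-06
ENSG00000106803	SC61B	Protein transport protein Sec61 beta subunit	2,46	8,9 E-05
ENSG00000137462	TLR2	Toll-like receptor 2 precursor	2,77	2,5 E-04
ENSG00000156127	BATF	ATF-like basic leucine zipper transcriptional factor B-ATF	3,13	2,3 E-04
ENSG00000171860	C3aR1	C3a anaphylatoxin chemotactic receptor	4,65	1,0 E-03
ENSG00000175756	AKIP	Aurora kinase A-interacting protein	5,68	8,7 E-04
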