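Ensembl ID	HUGO geneID	Full name	foldchange	p-value
ENSG00000172409	CLP1	Pre-mRNA cleavage complex II protein Clp1	0,47	0,001
ENSG00000197766	CDF	Complement factor D precursor	2,02	0,003
ENSG00000175592	FOSL1	Fos-related antigen 1	2,05	0,001
ENSG00000175602	DIPA	Delta-interacting protein A	2,05	0,001
ENSG00000166008	MAGEA9	Melanoma-associated antigen 9	2,37	0,001
ENSG00000136689	IL1RN	Interleukin-1 receptor antagonist protein precursor	2,41	0,003
ENSG00000179271	PLINP-1	Papillomavirus L2-interacting nuclear protein 1	2,69	0,002
ENSG00000181667	PTPRCAP	Protein tyrosine phosphatase receptor type C-associated protein	2,85	0,005
ENSG00000175756	AKIP	Aurora kinase A-interacting protein	3,01	0,001
ENSG00000196783	CCL3L1	Small inducible cytokine A3-like 1 precursor	3,25	0,002
ENSG00000129277	CCL4	Small inducible cytokine A4 precursor	5,87	0,001
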