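gene_id
ENSG00000156127
ENSG00000015475
ENSG00000171860
ENSG00000136689
ENSG00000106803
ENSG00000134802
ENSG00000232810
ENSG00000136244
ENSG00000169429
ENSG00000109320
ENSG00000108691
ENSG00000112096
ENSG00000090339
ENSG00000125538
ENSG00000110944
ENSG00000081041
ENSG00000163735
ENSG00000115594
ENSG00000100985
ENSG00000128342
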