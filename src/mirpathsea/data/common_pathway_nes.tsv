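pathway	NES_A	NES_B
KEGG_CELL_CYCLE	-2.4711	1.5168
KEGG_ERBB_SIGNALING	-2.3976	1.6308
KEGG_P53_SIGNALING	-2.396	1.6518
KEGG_TGF_BETA_SIGNALING	-2.3876	1.2741
KEGG_VEGF_SIGNALING	-2.3986	1.3925
KEGG_WNT_SIGNALING	-2.383	1.382
KEGG_NON_SMALL_CELL_LUNG_CANCER	-2.407	1.6235
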