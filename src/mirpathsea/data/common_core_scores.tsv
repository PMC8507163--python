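miRNA	KEGG_CELL_CYCLE	KEGG_ERBB_SIGNALING	KEGG_P53_SIGNALING	KEGG_TGF_BETA_SIGNALING	KEGG_VEGF_SIGNALING	KEGG_WNT_SIGNALING	KEGG_NON_SMALL_CELL_LUNG_CANCER
hsa-miR-106a	0.0495	0.1025	0.067	0	0	0	0.1145
hsa-miR-15b	0.076	0	0.085	0	0	0	0.121
hsa-miR-17	0.0775	0.1265	0.0885	0	0.079	-0.02	0.074
hsa-miR-103	0.015	0	0.0245	0	0	0.051	0.0612
hsa-miR-107	0.0075	0.033	0.007	0	0.0115	0	0.052
hsa-miR-133b	0	0.022	0	0	0	0	0.002
hsa-let-7d	0.059	0.03	0.0515	-0.08	0.03	0	0
hsa-miR-193a-3p	0	0.019	0	0	0.02	0	0
hsa-miR-16	0	0	-0.0625	0	-0.0775	0	0
hsa-miR-455-3p	0.0455	0	0	0.082	0	0	0.052
hsa-miR-15a	0	0	-0.032	0	0	-0.006	0
hsa-miR-361-5p	-0.0715	0	-0.0225	0	0	0	0
hsa-let-7e	-0.0915	0	0	0	0	-0.065	0
hsa-let-7c	-0.1535	-0.0845	-0.1355	-0.014	0	-0.001	-0.0645
hsa-miR-133a	0	0	-0.1325	-0.01185	-0.1448	-0.075	-0.075
hsa-let-7b	-0.1315	-0.1605	-0.1195	0	-0.1325	-0.028	0
hsa-miR-1285	-0.2455	0	-0.247	0	0	0.1155	-0.218
hsa-miR-1	-0.2115	-0.135	-0.226	-0.01585	0	-0.1525	0
hsa-miR-654-3p	-0.18	-0.1825	-0.178	0	0	0	0
hsa-miR-203	-0.188	0	0	0	0	0	-0.561
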