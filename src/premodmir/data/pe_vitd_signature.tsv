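mirna	regulation	fold_change	fdr
hsa-miR-885-5p	Upregulated	1.48	0.001
hsa-miR-122-5p	Upregulated	1.46	0.001
hsa-miR-34a-3p	Upregulated	1.55	0.001
hsa-miR-182-5p	Upregulated	1.25	0.001
hsa-miR-95-3p	Upregulated	1.20	0.003
hsa-miR-1244	Upregulated	1.18	0.005
hsa-miR-545-5p	Upregulated	1.18	0.006
hsa-miR-642a-5p	Upregulated	1.22	0.017
hsa-miR-365a-3p	Upregulated	1.26	0.025
hsa-miR-29a-5p	Downregulated	0.80	0.002
hsa-miR-424-5p	Downregulated	0.88	0.008
hsa-miR-135a-5p	Downregulated	0.77	0.013
hsa-miR-378a-5p	Downregulated	0.89	0.013
hsa-miR-145-3p	Downregulated	0.93	0.014
hsa-miR-31-5	Downregulated	0.88	0.023
hsa-miR-144-5p	Downregulated	0.93	0.040
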