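# Curated pairwise correlations for candidate ceRNA regulatory axes in three
# digestive cancers (TCGA tumor-sample co-expression exports at gene-symbol
# resolution). Columns: Pearson r and two-sided p for mRNA-miRNA (r_mm, p_mm),
# miRNA-lncRNA (r_ml, p_ml) and mRNA-lncRNA (r_lm, p_lm).
# Note: the GINS1/miR-139-5p/LINC00534 mRNA-lncRNA p-value is recorded as
# 1.02e-04; the source export printed it with a positive exponent (1.02e+04),
# an impossible value for a probability, so the exponent sign is corrected.
cancer	mRNA	miRNA	lncRNA	r_mm	p_mm	r_ml	p_ml	r_lm	p_lm
STAD	HMGA2	miR-490-3p	PVT1	-0.106	4.19e-02	-0.124	1.69e-02	0.208	5.12e-05
LIHC	TOP2A	miR-139-5p	DLX6-AS1	-0.472	6.00e-22	-0.183	4.07e-04	0.286	1.86e-08
LIHC	DSN1	miR-139-5p	DLX6-AS1	-0.351	3.63e-12	-0.183	4.07e-04	0.240	2.75e-06
LIHC	GINS1	miR-139-5p	DLX6-AS1	-0.472	5.98e-22	-0.183	4.07e-04	0.322	1.86e-10
LIHC	CCNB1	miR-139-5p	DLX6-AS1	-0.547	2.69e-30	-0.183	4.07e-04	0.306	1.57e-09
LIHC	RACGAP1	miR-139-5p	DLX6-AS1	-0.431	3.84e-18	-0.183	4.07e-04	0.326	1.09e-10
LIHC	CDCA8	miR-139-5p	DLX6-AS1	-0.513	3.18e-26	-0.183	4.07e-04	0.247	1.35e-06
LIHC	KPNA2	miR-139-5p	DLX6-AS1	-0.49	8.91e-24	-0.183	4.07e-04	0.274	7.15e-08
LIHC	TOP2A	miR-139-5p	PVT1	-0.472	6.00e-22	-0.24	2.94e-06	0.133	1.03e-02
LIHC	GINS1	miR-139-5p	PVT1	-0.472	5.98e-22	-0.24	2.94e-06	0.126	1.48e-02
LIHC	CCNB1	miR-139-5p	PVT1	-0.547	2.69e-30	-0.24	2.94e-06	0.264	2.12e-07
LIHC	RACGAP1	miR-139-5p	PVT1	-0.431	3.84e-18	-0.24	2.94e-06	0.190	2.16e-04
LIHC	CDCA8	miR-139-5p	PVT1	-0.513	3.18e-26	-0.24	2.94e-06	0.172	8.35e-04
LIHC	KPNA2	miR-139-5p	PVT1	-0.49	8.91e-24	-0.24	2.94e-06	0.287	1.51e-08
LIHC	TOP2A	miR-139-5p	LINC00534	-0.472	6.00e-22	-0.195	1.63e-04	0.224	1.21e-05
LIHC	DSN1	miR-139-5p	LINC00534	-0.351	3.63e-12	-0.195	1.63e-04	0.147	4.45e-03
LIHC	GINS1	miR-139-5p	LINC00534	-0.472	5.98e-22	-0.195	1.63e-04	0.226	1.02e-04
LIHC	CCNB1	miR-139-5p	LINC00534	-0.547	2.69e-30	-0.195	1.63e-04	0.239	2.94e-06
LIHC	RACGAP1	miR-139-5p	LINC00534	-0.431	3.84e-18	-0.195	1.63e-04	0.211	3.93e-04
LIHC	CDCA8	miR-139-5p	LINC00534	-0.513	3.18e-26	-0.195	1.63e-04	0.275	6.13e-08
LIHC	KPNA2	miR-139-5p	LINC00534	-0.49	8.91e-24	-0.195	1.63e-04	0.214	3.07e-04
LIHC	CDCA5	miR-490-3p	DSCR9	-0.154	2.94e-03	-0.103	4.82e-02	0.445	1.32e-19
LIHC	CDCA5	miR-490-3p	WASIR2	-0.154	2.94e-03	-0.124	1.67e-02	0.406	2.66e-16
LIHC	NDRG2	miR-338-3p	LINC00402	-0.122	1.85e-02	-0.203	8.09e-05	0.29	1.05e-08
COAD	GAB1	miR-142-3p	STRCP1	-0.291	3.08e-10	-0.158	7.69e-04	0.225	7.67e-07
COAD	GAB1	miR-142-3p	LINC00488	-0.291	3.08e-10	-0.138	3.44e-03	0.225	7.85e-07
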