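cell_line	node	degree	betweenness	is_hub	is_bottleneck
A549	ILF3	3	0.343	-	+
A549	PCNA	10	0.123	+	-
A549	FN1	18	0.069	+	-
A549	RAN	7	0.421	-	+
A549	TOP2A	2	0.481	-	+
A549	HSP90AA1	10	0.375	+	+
A549	HSP90AB1	6	0.212	-	-
A549	ICT1	21	0.072	+	-
A549	SUMO1	15	0.558	+	+
A549	SUMO2	10	0.027	+	-
A549	YWHAB	7	0.339	-	+
A549	YWHAE	2	0.295	-	-
A549	YWHAZ	20	0.319	+	+
A549	KHDRBS1	5	0.069	-	-
A549	CSNK2A1	8	0.722	-	+
A549	EGFR	16	0.155	+	-
A549	ATF2	11	0.030	+	-
A549	GRB2	9	0.024	-	-
A549	HTT	11	0.045	+	-
A549	LRRK2	11	0.033	+	-
A549	MDM2	13	0.040	+	-
A549	MYC	12	0.215	+	-
A549	PRMT1	5	0.332	-	+
A549	RANGAP1	2	0.399	-	+
A549	XPO5	3	0.347	-	+
SW900	ILF3	3	0.025	-	-
SW900	PCNA	8	0.028	-	-
SW900	FN1	12	0.058	+	-
SW900	RAN	2	0.003	-	-
SW900	TOP2A	2	0.454	-	+
SW900	HSP90AA1	11	0.570	+	+
SW900	HSP90AB1	6	0.535	-	+
SW900	ICT1	22	0.075	+	-
SW900	SUMO1	18	0.621	+	+
SW900	SUMO2	6	0.020	-	-
SW900	YWHAB	8	0.365	-	+
SW900	YWHAE	2	0.328	-	+
SW900	YWHAZ	22	0.361	+	+
SW900	KHDRBS1	5	0.421	-	+
SW900	CSNK2A1	8	0.509	-	+
SW900	EGFR	23	0.492	+	+
SW900	ATF2	6	0.017	-	-
SW900	GRB2	10	0.413	+	+
SW900	HTT	9	0.022	-	-
SW900	LRRK2	12	0.133	+	-
SW900	MDM2	13	0.080	+	-
SW900	MYC	17	0.056	+	-
SW900	PRMT1	6	0.117	-	-
SW900	HIF1A	4	0.508	-	+
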