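number	name	region	subnetwork	ba	x	y	z	radius_mm
1	dDMN_1_ROI	Medial frontal gyrus	dDMN	10	0	49	12	6
2	dDMN_2_ROI	Left angular gyrus	dDMN	39	-48	-73	32	6
3	dDMN_3_ROI	Right media frontal gyrus	dDMN	8	18	38	51	6
4	dDMN_4_ROI	Precuneus	dDMN	31	0	-57	30	6
5	dDMN_5_ROI	Cingulate gyrus	dDMN	24	0	-17	35	6
6	dDMN_6_ROI	Right angular gyrus	dDMN	39	48	-66	29	6
7	dDMN_7_ROI	Thalamus	dDMN		-6	-6	3	6
8	dDMN_8_ROI	Left parahippocampal gyrus	dDMN	35	-24	-37	-9	6
9	dDMN_9_ROI	Right parahippocampal gyrus	dDMN	35	24	-21	-23	6
10	pDMN_1_ROI	Posterior cingulate	pDMN	23	0	-35	28	6
11	pDMN_2_ROI	Precuneus	pDMN	7	0	-76	38	6
12	pDMN_3_ROI	Left inferior parietal lobule	pDMN	40	-39	-64	46	6
13	pDMN_4_ROI	Right inferior parietal lobule	pDMN	40	39	-64	46	6
14	vDMN_1_ROI	Left posterior cingulate	vDMN	30	-12	-62	10	6
15	vDMN_2_ROI	Left middle frontal gyrus	vDMN	6	-27	6	59	6
16	vDMN_3_ROI	Left parahippocampal gyrus	vDMN	37	-30	-39	-20	6
17	vDMN_4_ROI	Left angular gyrus	vDMN	19	-36	-88	28	6
18	vDMN_5_ROI	Right posterior cingulate	vDMN	30	15	-56	13	6
19	vDMN_6_ROI	Precuneus	vDMN	7	-6	-61	56	6
20	vDMN_7_ROI	Right middle frontal gyrus	vDMN	6	24	26	47	6
21	vDMN_8_ROI	Right parahippocampal gyrus	vDMN	37	27	-33	-23	6
22	vDMN_9_ROI	Right angular gyrus	vDMN	19	42	-79	28	6
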