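label_id	name	abbreviation	x	y	z
1	Frontal Pole Right	FP r	26	52	8
2	Frontal Pole Left	FP l	-25	53	8
3	Insular Cortex Right	IC r	37	3	0
4	Insular Cortex Left	IC l	-36	1	0
5	Superior Frontal Gyrus Right	SFG r	15	18	57
6	Superior Frontal Gyrus Left	SFG l	-14	19	56
7	Middle Frontal Gyrus Right	MidFG r	39	19	43
8	Middle Frontal Gyrus Left	MidFG l	-38	18	42
9	Inferior Frontal Gyrus, pars triangularis Right	IFG tri r	52	28	8
10	Inferior Frontal Gyrus, pars triangularis Left	IFG tri l	-50	28	9
11	Inferior Frontal Gyrus, pars opercularis Right	IFG oper r	52	15	16
12	Inferior Frontal Gyrus, pars opercularis Left	IFG oper l	-51	15	15
13	Precentral Gyrus Right	PreCG r	35	-11	50
14	Precentral Gyrus Left	PreCG l	-34	-12	49
15	Temporal Pole Right	TP r	41	13	-30
16	Temporal Pole Left	TP l	-40	11	-30
17	Superior Temporal Gyrus, anterior division Right	aSTG r	58	-1	-10
18	Superior Temporal Gyrus, anterior division Left	aSTG l	-56	-4	-8
19	Superior Temporal Gyrus, posterior division Right	pSTG r	61	-24	2
20	Superior Temporal Gyrus, posterior division Left	pSTG l	-62	-29	4
21	Middle Temporal Gyrus, anterior division Right	aMTG r	58	-2	-25
22	Middle Temporal Gyrus, anterior division Left	aMTG l	-57	-4	-22
23	Middle Temporal Gyrus, posterior division Right	pMTG r	61	-23	-12
24	Middle Temporal Gyrus, posterior division Left	pMTG l	-61	-27	-11
25	Middle Temporal Gyrus, temporooccipital part Right	toMTG r	58	-49	2
26	Middle Temporal Gyrus, temporooccipital part Left	toMTG l	-58	-53	1
27	Inferior Temporal Gyrus, anterior division Right	aITG r	46	-2	-41
28	Inferior Temporal Gyrus, anterior division Left	aITG l	-48	-5	-39
29	Inferior Temporal Gyrus, posterior division Right	pITG r	53	-23	-28
30	Inferior Temporal Gyrus, posterior division Left	pITG l	-53	-28	-26
31	Inferior Temporal Gyrus, temporooccipital part Right	toITG r	54	50	-17
32	Inferior Temporal Gyrus, temporooccipital part Left	toITG l	-52	-53	-17
33	Postcentral Gyrus Right	PostCG r	38	-26	53
34	Postcentral Gyrus Left	PostCG l	-38	-28	52
35	Superior Parietal Lobule Right	SPL r	29	-48	59
36	Superior Parietal Lobule Left	SPL l	-29	-49	57
37	Supramarginal Gyrus, anterior division Right	aSMG r	58	-27	38
38	Supramarginal Gyrus, anterior division Left	aSMG l	-57	-33	37
39	Supramarginal Gyrus, posterior division Right	pSMG r	55	-40	34
40	Supramarginal Gyrus, posterior division Left	pSMG l	-55	-46	33
41	Angular Gyrus Right	AG r	52	-52	32
42	Angular Gyrus Left	AG l	-50	-56	30
43	Lateral Occipital Cortex, superior division Right	sLOC r	33	-71	39
44	Lateral Occipital Cortex, superior division Left	sLOC l	-32	-73	38
45	Lateral Occipital Cortex, inferior division Right	iLOC r	46	-74	-2
46	Lateral Occipital Cortex, inferior division Left	iLOC l	-45	-76	-2
47	Intracalcarine Cortex Right	ICC r	12	-74	8
48	Intracalcarine Cortex Left	ICC l	-10	-75	8
49	Frontal Medial Cortex	MedFC	0	43	-19
50	Supplementary Motor Cortex Right	SMA r	6	-3	58
51	Supplementary Motor Cortex Left	SMA l	-5	-3	56
52	Subcallosal Cortex	SubCalC	0	21	-15
53	Paracingulate Gyrus Right	PaCiG r	7	37	23
54	Paracingulate Gyrus Left	PaCiG l	-6	37	21
55	Cingulate Gyrus, anterior division	AC	1	18	24
56	Cingulate Gyrus, posterior division	PC	1	-37	30
57	Precuneous Cortex	Precuneous	1	-59	38
58	Cuneal Cortex Right	Cuneal r	9	-79	28
59	Cuneal Cortex Left	Cuneal l	-8	-80	27
60	Frontal Orbital Cortex Right	FOrb r	29	23	-16
61	Frontal Orbital Cortex Left	FOrb l	-30	24	-17
62	Parahippocampal Gyrus, anterior division Right	aPaHC r	22	-8	-30
63	Parahippocampal Gyrus, anterior division Left	aPaHC l	-22	-9	-30
64	Parahippocampal Gyrus, posterior division Right	pPaHC r	23	-31	-17
65	Parahippocampal Gyrus, posterior division Left	pPaHC l	-22	-32	-17
66	Lingual Gyrus Right	LG r	14	-63	-5
67	Lingual Gyrus Left	LG l	-12	-66	-5
68	Temporal Fusiform Cortex, anterior division Right	aTFusC r	31	-3	-42
69	Temporal Fusiform Cortex, anterior division Left	aTFusC l	-32	-4	-42
70	Temporal Fusiform Cortex, posterior division Right	pTFusC r	36	-24	-28
71	Temporal Fusiform Cortex, posterior division Left	pTFusC l	-36	-30	-25
72	Temporal Occipital Fusiform Cortex Right	TOFusC r	35	-50	-17
73	Temporal Occipital Fusiform Cortex Left	TOFusC l	-33	-54	-16
74	Occipital Fusiform Gyrus Right	OFusG r	27	-75	-12
75	Occipital Fusiform Gyrus Left	OFusG l	-27	-77	-14
76	Frontal Operculum Cortex Right	FO r	41	19	5
77	Frontal Operculum Cortex Left	FO l	-40	18	5
78	Central Operculum Cortex Right	CO r	49	-6	11
79	Central Operculum Cortex Left	CO l	-48	-9	12
80	Parietal Operculum Cortex Right	PO r	49	-28	22
81	Parietal Operculum Cortex Left	PO l	-48	-32	20
82	Planum Polare Right	PP r	48	-4	-7
83	Planum Polare Left	PP l	-47	-6	-7
84	Heschl's Gyrus Right	HG r	46	-17	7
85	Heschl's Gyrus Left	HG l	-45	-20	7
86	Planum Temporale Right	PT r	55	-25	12
87	Planum Temporale Left	PT l	-53	-30	11
88	Supracalcarine Cortex Right	SCC r	8	-74	14
89	Supracalcarine Cortex Left	SCC l	-8	-73	15
90	Occipital Pole Right	OP r	18	-95	8
91	Occipital Pole Left	OP l	-17	-97	7
92	Thalamus Right	Thalamus r	11	-18	7
93	Thalamus Left	Thalamus l	-10	-19	6
94	Caudate Right	Caudate r	13	10	10
95	Caudate Left	Caudate l	-13	9	10
96	Putamen Right	Putamen r	25	2	0
97	Putamen Left	Putamen l	-25	0	0
98	Palladium Right	Palladium r	20	-4	-1
99	Palladium Left	Palladium l	-19	-5	-1
100	Hippocampus Right	Hippocampus r	26	-21	-14
101	Hippocampus Left	Hippocampus l	-25	-23	-14
102	Amygdala Right	Amygdala r	23	-4	-18
103	Amygdala Left	Amygdala l	-23	-5	-18
104	Accubens Right	Accubens r	9	12	-7
105	Accubens Left	Accubens l	-9	11	-7
106	Brainstem	Brainstem	0	-30	-35
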