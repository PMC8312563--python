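index	abbreviation	name	class
0	PreCG.L	Precentral gyrus (L)	primary
1	PreCG.R	Precentral gyrus (R)	primary
2	SFGdor.L	Superior frontal gyrus, dorsolateral (L)	association
3	SFGdor.R	Superior frontal gyrus, dorsolateral (R)	association
4	ORBsup.L	Superior frontal gyrus, orbital (L)	paralimbic
5	ORBsup.R	Superior frontal gyrus, orbital (R)	paralimbic
6	MFG.L	Middle frontal gyrus (L)	association
7	MFG.R	Middle frontal gyrus (R)	association
8	ORBmid.L	Middle frontal gyrus, orbital (L)	paralimbic
9	ORBmid.R	Middle frontal gyrus, orbital (R)	paralimbic
10	IFGoperc.L	Inferior frontal gyrus, opercular (L)	association
11	IFGoperc.R	Inferior frontal gyrus, opercular (R)	association
12	IFGtriang.L	Inferior frontal gyrus, triangular (L)	association
13	IFGtriang.R	Inferior frontal gyrus, triangular (R)	association
14	ORBinf.L	Inferior frontal gyrus, orbital (L)	paralimbic
15	ORBinf.R	Inferior frontal gyrus, orbital (R)	paralimbic
16	ROL.L	Rolandic operculum (L)	association
17	ROL.R	Rolandic operculum (R)	association
18	SMA.L	Supplementary motor area (L)	association
19	SMA.R	Supplementary motor area (R)	association
20	OLF.L	Olfactory cortex (L)	paralimbic
21	OLF.R	Olfactory cortex (R)	paralimbic
22	SFGmed.L	Superior frontal gyrus, medial (L)	association
23	SFGmed.R	Superior frontal gyrus, medial (R)	association
24	ORBsupmed.L	Superior frontal gyrus, medial orbital (L)	paralimbic
25	ORBsupmed.R	Superior frontal gyrus, medial orbital (R)	paralimbic
26	REC.L	Gyrus rectus (L)	paralimbic
27	REC.R	Gyrus rectus (R)	paralimbic
28	INS.L	Insula (L)	paralimbic
29	INS.R	Insula (R)	paralimbic
30	ACG.L	Anterior cingulate gyrus (L)	paralimbic
31	ACG.R	Anterior cingulate gyrus (R)	paralimbic
32	DCG.L	Median cingulate gyrus (L)	paralimbic
33	DCG.R	Median cingulate gyrus (R)	paralimbic
34	PCG.L	Posterior cingulate gyrus (L)	paralimbic
35	PCG.R	Posterior cingulate gyrus (R)	paralimbic
36	HIP.L	Hippocampus (L)	limbic
37	HIP.R	Hippocampus (R)	limbic
38	PHG.L	Parahippocampal gyrus (L)	paralimbic
39	PHG.R	Parahippocampal gyrus (R)	paralimbic
40	AMYG.L	Amygdala (L)	limbic
41	AMYG.R	Amygdala (R)	limbic
42	CAL.L	Calcarine fissure and surrounding cortex (L)	primary
43	CAL.R	Calcarine fissure and surrounding cortex (R)	primary
44	CUN.L	Cuneus (L)	association
45	CUN.R	Cuneus (R)	association
46	LING.L	Lingual gyrus (L)	association
47	LING.R	Lingual gyrus (R)	association
48	SOG.L	Superior occipital gyrus (L)	association
49	SOG.R	Superior occipital gyrus (R)	association
50	MOG.L	Middle occipital gyrus (L)	association
51	MOG.R	Middle occipital gyrus (R)	association
52	IOG.L	Inferior occipital gyrus (L)	association
53	IOG.R	Inferior occipital gyrus (R)	association
54	FFG.L	Fusiform gyrus (L)	association
55	FFG.R	Fusiform gyrus (R)	association
56	PoCG.L	Postcentral gyrus (L)	primary
57	PoCG.R	Postcentral gyrus (R)	primary
58	SPG.L	Superior parietal gyrus (L)	association
59	SPG.R	Superior parietal gyrus (R)	association
60	IPL.L	Inferior parietal lobule (L)	association
61	IPL.R	Inferior parietal lobule (R)	association
62	SMG.L	Supramarginal gyrus (L)	association
63	SMG.R	Supramarginal gyrus (R)	association
64	ANG.L	Angular gyrus (L)	association
65	ANG.R	Angular gyrus (R)	association
66	PCUN.L	Precuneus (L)	association
67	PCUN.R	Precuneus (R)	association
68	PCL.L	Paracentral lobule (L)	association
69	PCL.R	Paracentral lobule (R)	association
70	CAU.L	Caudate nucleus (L)	subcortical
71	CAU.R	Caudate nucleus (R)	subcortical
72	PUT.L	Putamen (L)	subcortical
73	PUT.R	Putamen (R)	subcortical
74	PAL.L	Pallidum (L)	subcortical
75	PAL.R	Pallidum (R)	subcortical
76	THA.L	Thalamus (L)	subcortical
77	THA.R	Thalamus (R)	subcortical
78	HES.L	Heschl gyrus (L)	primary
79	HES.R	Heschl gyrus (R)	primary
80	STG.L	Superior temporal gyrus (L)	association
81	STG.R	Superior temporal gyrus (R)	association
82	TPOsup.L	Temporal pole, superior temporal gyrus (L)	paralimbic
83	TPOsup.R	Temporal pole, superior temporal gyrus (R)	paralimbic
84	MTG.L	Middle temporal gyrus (L)	association
85	MTG.R	Middle temporal gyrus (R)	association
86	TPOmid.L	Temporal pole, middle temporal gyrus (L)	paralimbic
87	TPOmid.R	Temporal pole, middle temporal gyrus (R)	paralimbic
88	ITG.L	Inferior temporal gyrus (L)	association
89	ITG.R	Inferior temporal gyrus (R)	association
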