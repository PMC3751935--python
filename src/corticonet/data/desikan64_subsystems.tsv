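region_id	hemisphere	abbreviation	full_name	subsystem
0	left	SFC	superior frontal cortex	strategic_executive
1	left	rMFC	rostral middle frontal cortex	strategic_executive
2	left	cMFC	caudal middle frontal cortex	strategic_executive
3	left	IFCa	inferior frontal cortex - pars orbitalis	language
4	left	IFCb	inferior frontal cortex - pars triangularis	language
5	left	IFCc	inferior frontal cortex - pars opercularis	language
6	left	LOFC	lateral orbitofrontal cortex	strategic_executive
7	left	MOFC	medial orbitofrontal cortex	mnemonic_emotional
8	left	preCen	precentral cortex	sensorimotor
9	left	paraCen	paracentral cortex	sensorimotor
10	left	Fpol	frontal pole	strategic_executive
11	left	STC	superior temporal cortex	language
12	left	MTC	middle temporal cortex	language
13	left	ITC	inferior temporal cortex	mnemonic_emotional
14	left	TTC	transverse temporal cortex	language
15	left	Fus	fusiform cortex	mnemonic_emotional
16	left	Ento	entorhinal cortex	mnemonic_emotional
17	left	paraHi	parahippocampal cortex	mnemonic_emotional
18	left	Tpol	temporal pole	mnemonic_emotional
19	left	SPC	superior parietal cortex	sensorimotor
20	left	IPC	inferior parietal cortex	sensorimotor
21	left	supM	supramarginal cortex	language
22	left	postCen	postcentral cortex	sensorimotor
23	left	preCun	precuneus cortex	strategic_executive
24	left	rACC	rostral anterior cingulate cortex	mnemonic_emotional
25	left	cACC	caudal anterior cingulate cortex	strategic_executive
26	left	PCC	posterior cingulate cortex	mnemonic_emotional
27	left	ICC	isthmus cingulate cortex	mnemonic_emotional
28	left	LOC	lateral occipital cortex	visual
29	left	Cun	cuneus cortex	visual
30	left	PeriCal	pericalcarine cortex	visual
31	left	Lin	lingual cortex	visual
32	right	SFC	superior frontal cortex	strategic_executive
33	right	rMFC	rostral middle frontal cortex	strategic_executive
34	right	cMFC	caudal middle frontal cortex	strategic_executive
35	right	IFCa	inferior frontal cortex - pars orbitalis	language
36	right	IFCb	inferior frontal cortex - pars triangularis	language
37	right	IFCc	inferior frontal cortex - pars opercularis	language
38	right	LOFC	lateral orbitofrontal cortex	strategic_executive
39	right	MOFC	medial orbitofrontal cortex	mnemonic_emotional
40	right	preCen	precentral cortex	sensorimotor
41	right	paraCen	paracentral cortex	sensorimotor
42	right	Fpol	frontal pole	strategic_executive
43	right	STC	superior temporal cortex	language
44	right	MTC	middle temporal cortex	language
45	right	ITC	inferior temporal cortex	mnemonic_emotional
46	right	TTC	transverse temporal cortex	language
47	right	Fus	fusiform cortex	mnemonic_emotional
48	right	Ento	entorhinal cortex	mnemonic_emotional
49	right	paraHi	parahippocampal cortex	mnemonic_emotional
50	right	Tpol	temporal pole	mnemonic_emotional
51	right	SPC	superior parietal cortex	sensorimotor
52	right	IPC	inferior parietal cortex	sensorimotor
53	right	supM	supramarginal cortex	language
54	right	postCen	postcentral cortex	sensorimotor
55	right	preCun	precuneus cortex	strategic_executive
56	right	rACC	rostral anterior cingulate cortex	mnemonic_emotional
57	right	cACC	caudal anterior cingulate cortex	strategic_executive
58	right	PCC	posterior cingulate cortex	mnemonic_emotional
59	right	ICC	isthmus cingulate cortex	mnemonic_emotional
60	right	LOC	lateral occipital cortex	visual
61	right	Cun	cuneus cortex	visual
62	right	PeriCal	pericalcarine cortex	visual
63	right	Lin	lingual cortex	visual
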