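id	mutation	class	subtype	human_flag
0	I136V	PAT	IEM	1
1	S211P	PAT	IEM	1
2	F216S	PAT	IEM	1
3	I234T	PAT	IEM	1
4	S241T	PAT	IEM	1
5	N395K	PAT	IEM	1
6	V400M	PAT	IEM	1
7	L823R	PAT	IEM	1
8	I848T	PAT	IEM	1
9	L858F	PAT	IEM	1
10	L858H	PAT	IEM	1
11	A863P	PAT	IEM	1
12	V872G	PAT	IEM	1
13	P1308L	PAT	IEM	1
14	V1316A	PAT	IEM	1
15	F1449V	PAT	IEM	1
16	W1538R	PAT	IEM	1
17	A1746G	PAT	IEM	1
18	R185H	PAT	SFN	1
19	I228M	PAT	SFN	1
20	I720K	PAT	SFN	1
21	I739V	PAT	SFN	1
22	G856D	PAT	SFN	1
23	M1532I	PAT	SFN	1
24	R996C	PAT	PEPD	1
25	V1298F	PAT	PEPD	1
26	V1298D	PAT	PEPD	1
27	V1299F	PAT	PEPD	1
28	G1607R	PAT	PEPD	1
29	M1627K	PAT	PEPD	1
30	T1596I	PAT	PDN	1
31	D623N	NEUTRAL	nABN	1
32	K655R	NEUTRAL	nABN	1
33	M932L	NEUTRAL	nABN	1
34	V991L	NEUTRAL	nABN	1
35	V194I	NEUTRAL	dbSNP	1
36	L201V	NEUTRAL	dbSNP	1
37	N206D	NEUTRAL	dbSNP	1
38	T370M	NEUTRAL	dbSNP	1
39	P610T	NEUTRAL	dbSNP	1
40	E759D	NEUTRAL	dbSNP	1
41	A766V	NEUTRAL	dbSNP	1
42	V795I	NEUTRAL	dbSNP	1
43	E1160Q	NEUTRAL	dbSNP	1
44	K1176R	NEUTRAL	dbSNP	1
45	T1398M	NEUTRAL	dbSNP	1
46	I1399V	NEUTRAL	dbSNP	1
47	D1411N	NEUTRAL	dbSNP	1
48	S1419N	NEUTRAL	dbSNP	1
49	V1428I	NEUTRAL	dbSNP	1
50	M1532V	NEUTRAL	dbSNP	1
51	H1560Y	NEUTRAL	dbSNP	1
52	V37I	NEUTRAL	pseudo	0
53	A55T	NEUTRAL	pseudo	0
54	I62V	NEUTRAL	pseudo	0
55	S67N	NEUTRAL	pseudo	0
56	T101S	NEUTRAL	pseudo	0
57	N146S	NEUTRAL	pseudo	0
58	V231I	NEUTRAL	pseudo	0
59	L245M	NEUTRAL	pseudo	0
60	I253V	NEUTRAL	pseudo	0
61	S268T	NEUTRAL	pseudo	0
62	A389S	NEUTRAL	pseudo	0
63	T464S	NEUTRAL	pseudo	0
64	S490N	NEUTRAL	pseudo	0
65	A505T	NEUTRAL	pseudo	0
66	V526I	NEUTRAL	pseudo	0
67	N641S	NEUTRAL	pseudo	0
68	I683V	NEUTRAL	pseudo	0
69	T721S	NEUTRAL	pseudo	0
70	A744S	NEUTRAL	pseudo	0
71	V781I	NEUTRAL	pseudo	0
72	S802T	NEUTRAL	pseudo	0
73	I931V	NEUTRAL	pseudo	0
74	L1051M	NEUTRAL	pseudo	0
75	V1073I	NEUTRAL	pseudo	0
76	T1123S	NEUTRAL	pseudo	0
77	N1245S	NEUTRAL	pseudo	0
78	I1577V	NEUTRAL	pseudo	0
79	A1632S	NEUTRAL	pseudo	0
80	V1689I	NEUTRAL	pseudo	0
81	S1712T	NEUTRAL	pseudo	0
82	T1800S	NEUTRAL	pseudo	0
83	N1871S	NEUTRAL	pseudo	0
84	V1950I	NEUTRAL	pseudo	0
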