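id	composition	label
1	HexNAc(2)Hex(5)	high_mannose
2	HexNAc(2)Hex(6)	high_mannose
3	HexNAc(2)Hex(7)	high_mannose
4	HexNAc(2)Hex(8)	high_mannose
5	HexNAc(2)Hex(9)	high_mannose
6	HexNAc(2)Hex(10)	high_mannose
7	HexNAc(2)Hex(11)	high_mannose
8	HexNAc(2)Hex(12)	high_mannose
9	HexNAc(2)Hex(1)	paucimannose
10	HexNAc(2)Hex(1)Fuc(1)	fucosylated
11	HexNAc(2)Hex(2)	paucimannose
12	HexNAc(2)Hex(2)Fuc(1)	fucosylated
13	HexNAc(2)Hex(3)	paucimannose
14	HexNAc(2)Hex(3)Fuc(1)	fucosylated
15	HexNAc(2)Hex(4)	paucimannose
16	HexNAc(2)Hex(4)Fuc(1)	fucosylated
17	HexNAc(2)Hex(4)Phospho(1)	M6P
18	HexNAc(2)Hex(5)Phospho(1)	M6P
19	HexNAc(2)Hex(6)Phospho(1)	M6P
20	HexNAc(2)Hex(7)Phospho(1)	M6P
21	HexNAc(2)Hex(8)Phospho(1)	M6P
22	HexNAc(2)Hex(9)Phospho(1)	M6P
23	HexNAc(2)Hex(6)Phospho(2)	M6P
24	HexNAc(2)Hex(7)Phospho(2)	M6P
25	HexNAc(2)Hex(8)Phospho(2)	M6P
26	HexNAc(3)Hex(3)	complex_hybrid
27	HexNAc(3)Hex(4)	complex_hybrid
28	HexNAc(3)Hex(5)	complex_hybrid
29	HexNAc(3)Hex(6)	complex_hybrid
30	HexNAc(3)Hex(7)	complex_hybrid
31	HexNAc(4)Hex(3)	complex_hybrid
32	HexNAc(4)Hex(4)	complex_hybrid
33	HexNAc(4)Hex(5)	complex_hybrid
34	HexNAc(4)Hex(6)	complex_hybrid
35	HexNAc(4)Hex(7)	complex_hybrid
36	HexNAc(5)Hex(3)	complex_hybrid
37	HexNAc(5)Hex(4)	complex_hybrid
38	HexNAc(5)Hex(5)	complex_hybrid
39	HexNAc(5)Hex(6)	complex_hybrid
40	HexNAc(5)Hex(7)	complex_hybrid
41	HexNAc(6)Hex(3)	complex_hybrid
42	HexNAc(6)Hex(4)	complex_hybrid
43	HexNAc(6)Hex(5)	complex_hybrid
44	HexNAc(6)Hex(6)	complex_hybrid
45	HexNAc(6)Hex(7)	complex_hybrid
46	HexNAc(3)Hex(3)Fuc(1)	fucosylated
47	HexNAc(3)Hex(4)Fuc(1)	fucosylated
48	HexNAc(3)Hex(5)Fuc(1)	fucosylated
49	HexNAc(3)Hex(6)Fuc(1)	fucosylated
50	HexNAc(3)Hex(7)Fuc(1)	fucosylated
51	HexNAc(4)Hex(3)Fuc(1)	fucosylated
52	HexNAc(4)Hex(4)Fuc(1)	fucosylated
53	HexNAc(4)Hex(5)Fuc(1)	fucosylated
54	HexNAc(4)Hex(6)Fuc(1)	fucosylated
55	HexNAc(4)Hex(7)Fuc(1)	fucosylated
56	HexNAc(5)Hex(3)Fuc(1)	fucosylated
57	HexNAc(5)Hex(4)Fuc(1)	fucosylated
58	HexNAc(5)Hex(5)Fuc(1)	fucosylated
59	HexNAc(5)Hex(6)Fuc(1)	fucosylated
60	HexNAc(5)Hex(7)Fuc(1)	fucosylated
61	HexNAc(6)Hex(3)Fuc(1)	fucosylated
62	HexNAc(6)Hex(4)Fuc(1)	fucosylated
63	HexNAc(6)Hex(5)Fuc(1)	fucosylated
64	HexNAc(6)Hex(6)Fuc(1)	fucosylated
65	HexNAc(6)Hex(7)Fuc(1)	fucosylated
66	HexNAc(2)Hex(5)Fuc(1)	fucosylated
67	HexNAc(2)Hex(6)Fuc(1)	fucosylated
68	HexNAc(2)Hex(7)Fuc(1)	fucosylated
69	HexNAc(3)Hex(4)NeuAc(1)	sialylated
70	HexNAc(3)Hex(4)NeuAc(2)	sialylated
71	HexNAc(3)Hex(5)NeuAc(1)	sialylated
72	HexNAc(3)Hex(5)NeuAc(2)	sialylated
73	HexNAc(3)Hex(6)NeuAc(1)	sialylated
74	HexNAc(3)Hex(6)NeuAc(2)	sialylated
75	HexNAc(3)Hex(7)NeuAc(1)	sialylated
76	HexNAc(3)Hex(7)NeuAc(2)	sialylated
77	HexNAc(4)Hex(4)NeuAc(1)	sialylated
78	HexNAc(4)Hex(4)NeuAc(2)	sialylated
79	HexNAc(4)Hex(5)NeuAc(1)	sialylated
80	HexNAc(4)Hex(5)NeuAc(2)	sialylated
81	HexNAc(4)Hex(6)NeuAc(1)	sialylated
82	HexNAc(4)Hex(6)NeuAc(2)	sialylated
83	HexNAc(4)Hex(7)NeuAc(1)	sialylated
84	HexNAc(4)Hex(7)NeuAc(2)	sialylated
85	HexNAc(5)Hex(4)NeuAc(1)	sialylated
86	HexNAc(5)Hex(4)NeuAc(2)	sialylated
87	HexNAc(5)Hex(5)NeuAc(1)	sialylated
88	HexNAc(5)Hex(5)NeuAc(2)	sialylated
89	HexNAc(5)Hex(6)NeuAc(1)	sialylated
90	HexNAc(5)Hex(6)NeuAc(2)	sialylated
91	HexNAc(5)Hex(7)NeuAc(1)	sialylated
92	HexNAc(5)Hex(7)NeuAc(2)	sialylated
93	HexNAc(3)Hex(4)Fuc(1)NeuAc(1)	sialylated
94	HexNAc(3)Hex(5)Fuc(1)NeuAc(1)	sialylated
95	HexNAc(3)Hex(6)Fuc(1)NeuAc(1)	sialylated
96	HexNAc(3)Hex(7)Fuc(1)NeuAc(1)	sialylated
97	HexNAc(4)Hex(4)Fuc(1)NeuAc(1)	sialylated
98	HexNAc(4)Hex(5)Fuc(1)NeuAc(1)	sialylated
99	HexNAc(4)Hex(6)Fuc(1)NeuAc(1)	sialylated
100	HexNAc(4)Hex(7)Fuc(1)NeuAc(1)	sialylated
101	HexNAc(5)Hex(4)Fuc(1)NeuAc(1)	sialylated
102	HexNAc(5)Hex(5)Fuc(1)NeuAc(1)	sialylated
103	HexNAc(5)Hex(6)Fuc(1)NeuAc(1)	sialylated
104	HexNAc(5)Hex(7)Fuc(1)NeuAc(1)	sialylated
105	HexNAc(5)Hex(6)NeuAc(3)	sialylated
106	HexNAc(5)Hex(7)NeuAc(3)	sialylated
107	HexNAc(5)Hex(8)NeuAc(3)	sialylated
108	HexNAc(6)Hex(6)NeuAc(3)	sialylated
109	HexNAc(6)Hex(7)NeuAc(3)	sialylated
110	HexNAc(6)Hex(8)NeuAc(3)	sialylated
111	HexNAc(4)Hex(5)Fuc(2)	fucosylated
112	HexNAc(4)Hex(6)Fuc(2)	fucosylated
113	HexNAc(5)Hex(5)Fuc(2)	fucosylated
114	HexNAc(5)Hex(6)Fuc(2)	fucosylated
115	HexNAc(6)Hex(5)Fuc(2)	fucosylated
116	HexNAc(6)Hex(6)Fuc(2)	fucosylated
117	HexNAc(6)Hex(7)Fuc(2)	fucosylated
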