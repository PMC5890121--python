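node_id	x	y	z	network
1	-25	-98	-12	SMN
2	27	-97	-13	SMN
3	24	32	-18	SMN
4	-56	-45	-24	SMN
5	8	41	-24	SMN
6	-21	-22	-20	SMN
7	17	-28	-17	SMN
8	-37	-29	-26	SMN
9	65	-24	-19	SMN
10	52	-34	-27	SMN
11	55	-31	-17	SMN
12	34	38	-12	SMN
13	-7	-52	61	SMN
14	-14	-18	40	SMN
15	0	-15	47	SMN
16	10	-2	45	SMN
17	-7	-21	65	SMN
18	-7	-33	72	SMN
19	13	-33	75	SMN
20	-54	-23	43	SMN
21	29	-17	71	SMN
22	10	-46	73	SMN
23	-23	-30	72	SMN
24	-40	-19	54	SMN
25	29	-39	59	SMN
26	50	-20	42	SMN
27	-38	-27	69	SMN
28	20	-29	60	SMN
29	44	-8	57	SMN
30	-29	-43	61	SMN
31	10	-17	74	SMN
32	22	-42	69	SMN
33	-45	-32	47	SMN
34	-21	-31	61	SMN
35	-13	-17	75	SMN
36	42	-20	55	CON
37	-38	-15	69	CON
38	-16	-46	73	CON
39	2	-28	60	CON
40	3	-17	58	CON
41	38	-17	45	CON
42	-49	-11	35	CON
43	36	-9	14	CON
44	51	-6	32	CON
45	-53	-10	24	CON
46	66	-8	25	CON
47	-3	2	53	CON
48	54	-28	34	CON
49	19	-8	64	CON
50	-16	-5	71	Aud
51	-10	-2	42	Aud
52	37	1	-4	Aud
53	13	-1	70	Aud
54	7	8	51	Aud
55	-45	0	9	Aud
56	49	8	-1	Aud
57	-34	3	4	Aud
58	-51	8	-2	Aud
59	-5	18	34	Aud
60	36	10	1	Aud
61	32	-26	13	Aud
62	65	-33	20	Aud
63	58	-16	7	DMN
64	-38	-33	17	DMN
65	-60	-25	14	DMN
66	-49	-26	5	DMN
67	43	-23	20	DMN
68	-50	-34	26	DMN
69	-53	-22	23	DMN
70	-55	-9	12	DMN
71	56	-5	13	DMN
72	59	-17	29	DMN
73	-30	-27	12	DMN
74	-41	-75	26	DMN
75	6	67	-4	DMN
76	8	48	-15	DMN
77	-13	-40	1	DMN
78	-18	63	-9	DMN
79	-46	-61	21	DMN
80	43	-72	28	DMN
81	-44	12	-34	DMN
82	46	16	-30	DMN
83	-68	-23	-16	DMN
84	-58	-26	-15	DMN
85	27	16	-17	DMN
86	-44	-65	35	DMN
87	-39	-75	44	DMN
88	-7	-55	27	DMN
89	6	-59	35	DMN
90	-11	-56	16	DMN
91	-3	-49	13	DMN
92	8	-48	31	DMN
93	15	-63	26	DMN
94	-2	-37	44	DMN
95	11	-54	17	DMN
96	52	-59	36	DMN
97	23	33	48	DMN
98	-10	39	52	DMN
99	-16	29	53	DMN
100	-35	20	51	DMN
101	22	39	39	DMN
102	13	55	38	DMN
103	-10	55	39	DMN
104	-20	45	39	DMN
105	6	54	16	DMN
106	6	64	22	DMN
107	-7	51	-1	DMN
108	9	54	3	DMN
109	-3	44	-9	DMN
110	8	42	-5	DMN
111	-11	45	8	DMN
112	-2	38	36	DMN
113	-3	42	16	DMN
114	-20	64	19	DMN
115	-8	48	23	DMN
116	65	-12	-19	DMN
117	-56	-13	-10	DMN
118	-58	-30	-4	DMN
119	65	-31	-9	DMN
120	-68	-41	-5	DMN
121	13	30	59	Vis
122	12	36	20	Vis
123	52	-2	-16	Vis
124	-26	-40	-8	Vis
125	27	-37	-13	Vis
126	-34	-38	-16	Vis
127	28	-77	-32	Vis
128	52	7	-30	Vis
129	-53	3	-27	Vis
130	47	-50	29	Vis
131	-49	-42	1	Vis
132	-31	19	-19	Vis
133	-2	-35	31	Vis
134	-7	-71	42	Vis
135	11	-66	42	Vis
136	4	-48	51	Vis
137	-46	31	-13	Vis
138	-10	11	67	Vis
139	49	35	-12	Vis
140	8	-91	-7	Vis
141	17	-91	-14	Vis
142	-12	-95	-13	Vis
143	18	-47	-10	Vis
144	40	-72	14	Vis
145	8	-72	11	Vis
146	-8	-81	7	Vis
147	-28	-79	19	Vis
148	20	-66	2	Vis
149	-24	-91	19	Vis
150	27	-59	-9	Vis
151	-15	-72	-8	Vis
152	-18	-68	5	FPN
153	43	-78	-12	FPN
154	-47	-76	-10	FPN
155	-14	-91	31	FPN
156	15	-87	37	FPN
157	29	-77	25	FPN
158	20	-86	-2	FPN
159	15	-77	31	FPN
160	-16	-52	-1	FPN
161	42	-66	-8	FPN
162	24	-87	24	FPN
163	6	-72	24	FPN
164	-42	-74	0	FPN
165	26	-79	-16	FPN
166	-16	-77	34	FPN
167	-3	-81	21	FPN
168	-40	-88	-6	FPN
169	37	-84	13	FPN
170	6	-81	6	FPN
171	-26	-90	3	FPN
172	-33	-79	-13	FPN
173	37	-81	1	FPN
174	-44	2	46	FPN
175	48	25	27	FPN
176	-47	11	23	FPN
177	-53	-49	43	SAN
178	-23	11	64	SAN
179	58	-53	-14	SAN
180	24	45	-15	SAN
181	34	54	-13	SAN
182	-21	41	-20	SAN
183	-18	-76	-24	SAN
184	17	-80	-34	SAN
185	35	-67	-34	SAN
186	47	10	33	SAN
187	-41	6	33	SAN
188	-42	38	21	SAN
189	38	43	15	SAN
190	49	-42	45	SAN
191	-28	-58	48	SAN
192	44	-53	47	SAN
193	32	14	56	SAN
194	37	-65	40	SAN
195	-42	-55	45	Sub
196	40	18	40	Sub
197	-34	55	4	Sub
198	-42	45	-2	Sub
199	33	-53	44	Sub
200	43	49	-2	Sub
201	-42	25	30	Sub
202	-3	26	44	Sub
203	11	-39	50	Sub
204	55	-45	37	Sub
205	42	0	47	Sub
206	31	33	26	Sub
207	48	22	10	Sub
208	-35	20	0	VAN
209	36	22	3	VAN
210	37	32	-2	VAN
211	34	16	-8	VAN
212	-11	26	25	VAN
213	-1	15	44	VAN
214	-28	52	21	VAN
215	0	30	27	VAN
216	5	23	37	VAN
217	10	22	27	DAN
218	31	56	14	DAN
219	26	50	27	DAN
220	-39	51	17	DAN
221	2	-24	30	DAN
222	6	-24	0	DAN
223	-2	-13	12	DAN
224	-10	-18	7	DAN
225	12	-17	8	DAN
226	-5	-28	-4	DAN
227	-22	7	-5	DAN
228	-15	4	8	Unassigned
229	31	-14	2	Unassigned
230	23	10	1	Unassigned
231	29	1	4	Unassigned
232	-31	-11	0	Unassigned
233	15	5	7	Unassigned
234	9	-4	6	Unassigned
235	54	-43	22	Unassigned
236	-56	-50	10	Unassigned
237	-55	-40	14	Unassigned
238	52	-33	8	Unassigned
239	51	-29	-4	Unassigned
240	56	-46	11	Unassigned
241	53	33	1	Unassigned
242	-49	25	-1	Unassigned
243	-16	-65	-20	Unassigned
244	-32	-55	-25	Unassigned
245	22	-58	-23	Unassigned
246	1	-62	-18	Unassigned
247	33	-12	-34	Unassigned
248	-31	-10	-36	Unassigned
249	49	-3	-38	Unassigned
250	-50	-7	-39	Unassigned
251	10	-62	61	Unassigned
252	-52	-63	5	Unassigned
253	-47	-51	-21	Unassigned
254	46	-47	-17	Unassigned
255	47	-30	49	Unassigned
256	22	-65	48	Unassigned
257	46	-59	4	Unassigned
258	25	-58	60	Unassigned
259	-33	-46	47	Unassigned
260	-27	-71	37	Unassigned
261	-32	-1	54	Unassigned
262	-42	-60	-9	Unassigned
263	-17	-59	64	Unassigned
264	29	-5	54	Unassigned
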