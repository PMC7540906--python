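sample_id	order	feeding_code
02	Rhabditida	1d
04	Rhabditida	1d
06	Rhabditida	1d
07	Rhabditida	1d
15	Rhabditida	1d
28	Rhabditida	1d
35	Rhabditida	1d
40	Rhabditida	1d
44	Rhabditida	1d
59	Rhabditida	1d
61	Rhabditida	1d
75	Rhabditida	1d
77	Rhabditida	1d
09	Dorylaimida	2
10	Dorylaimida	2
19	Dorylaimida	2
27	Dorylaimida	2
43	Dorylaimida	2
47	Dorylaimida	2
50	Dorylaimida	2
57	Dorylaimida	2
69	Dorylaimida	2
71	Dorylaimida	2
84	Dorylaimida	2
03	Dorylaimida	2
34	Dorylaimida	2
42	Dorylaimida	2
45	Dorylaimida	2
67	Dorylaimida	2
73	Dorylaimida	2
82	Dorylaimida	2
83	Dorylaimida	2
85	Dorylaimida	2
87	Dorylaimida	2
93	Dorylaimida	2
36	Dorylaimida	5,8
37	Dorylaimida	5,8
46	Dorylaimida	5,8
53	Dorylaimida	5,8
63	Dorylaimida	5,8
74	Dorylaimida	5,8
78	Dorylaimida	5,8
30	Triplonchida	1d
33	Triplonchida	1d
70	Triplonchida	1d
80	Triplonchida	1d
89	Rhabditida	1e
94	Rhabditida	1e
96	Rhabditida	1e
72	Dorylaimida	2
91	Dorylaimida	2
95	Dorylaimida	2
41	Dorylaimida	5,8
51	Dorylaimida	5,8
31	Triplonchida	3,6?
76	Triplonchida	3,6?
20	Rhabditida	3
88	Rhabditida	3
16	Rhabditida	1b
22	Rhabditida	1b
18	Triplonchida	3?
24	Triplonchida	3?
49	Dorylaimida	8?
68	Triplonchida	2
52	Plectida	3
01	Triplonchida	3,6?
56	Triplonchida	3?
25	Triplonchida	3,6?
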