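sample_id	region	sv_id
02	1	R1_SV_2
02	2	R2_SV_2
02	3	R3_SV_4
02	4	R4_SV_1
04	1	R1_SV_2
04	2	R2_SV_2
04	3	R3_SV_4
04	4	R4_SV_1
06	1	R1_SV_2
06	2	R2_SV_2
06	3	R3_SV_4
06	4	R4_SV_1
07	1	R1_SV_2
07	2	R2_SV_2
07	3	R3_SV_4
07	4	R4_SV_1
15	1	R1_SV_2
15	2	R2_SV_2
15	3	R3_SV_4
15	4	R4_SV_1
28	1	R1_SV_2
28	2	R2_SV_2
28	3	R3_SV_4
28	4	R4_SV_1
35	1	R1_SV_2
35	2	R2_SV_2
35	3	R3_SV_4
35	4	R4_SV_1
40	1	R1_SV_2
40	2	R2_SV_2
40	3	R3_SV_4
40	4	R4_SV_1
44	1	R1_SV_2
44	2	R2_SV_2
44	3	R3_SV_4
44	4	R4_SV_1
59	1	R1_SV_2
59	2	R2_SV_2
59	3	R3_SV_4
59	4	R4_SV_1
61	1	R1_SV_2
61	2	R2_SV_2
61	3	R3_SV_4
61	4	R4_SV_1
75	1	R1_SV_2
75	2	R2_SV_2
75	3	R3_SV_4
75	4	R4_SV_1
77	1	R1_SV_2
77	2	R2_SV_2
77	3	R3_SV_4
77	4	R4_SV_1
09	1	R1_SV_3
09	2	R2_SV_3
09	3	R3_SV_3
09	4	R4_SV_3
10	1	R1_SV_3
10	2	R2_SV_3
10	3	R3_SV_3
10	4	R4_SV_3
19	1	R1_SV_3
19	2	R2_SV_3
19	3	R3_SV_3
19	4	R4_SV_3
27	1	R1_SV_3
27	2	R2_SV_3
27	3	R3_SV_3
27	4	R4_SV_3
43	1	R1_SV_3
43	2	R2_SV_3
43	3	R3_SV_3
43	4	R4_SV_3
47	1	R1_SV_3
47	2	R2_SV_3
47	3	R3_SV_3
47	4	R4_SV_3
50	1	R1_SV_3
50	2	R2_SV_3
50	3	R3_SV_3
50	4	R4_SV_3
57	1	R1_SV_3
57	2	R2_SV_3
57	3	R3_SV_3
57	4	R4_SV_3
69	1	R1_SV_3
69	2	R2_SV_3
69	3	R3_SV_3
69	4	R4_SV_3
71	1	R1_SV_3
71	2	R2_SV_3
71	3	R3_SV_3
71	4	R4_SV_3
84	1	R1_SV_3
84	2	R2_SV_3
84	3	R3_SV_3
84	4	R4_SV_3
03	1	R1_SV_1
03	2	R2_SV_1
03	3	R3_SV_1
03	4	R4_SV_2
34	1	R1_SV_1
34	2	R2_SV_1
34	3	R3_SV_1
34	4	R4_SV_2
42	1	R1_SV_1
42	2	R2_SV_1
42	3	R3_SV_1
42	4	R4_SV_2
45	1	R1_SV_1
45	2	R2_SV_1
45	3	R3_SV_1
45	4	R4_SV_2
67	1	R1_SV_1
67	2	R2_SV_1
67	3	R3_SV_1
67	4	R4_SV_2
73	1	R1_SV_1
73	2	R2_SV_1
73	3	R3_SV_1
73	4	R4_SV_2
82	1	R1_SV_1
82	2	R2_SV_1
82	3	R3_SV_1
82	4	R4_SV_2
83	1	R1_SV_1
83	2	R2_SV_1
83	3	R3_SV_1
83	4	R4_SV_2
85	1	R1_SV_1
85	2	R2_SV_1
85	3	R3_SV_1
85	4	R4_SV_2
87	1	R1_SV_1
87	2	R2_SV_1
87	3	R3_SV_1
87	4	R4_SV_2
93	1	R1_SV_1
93	2	R2_SV_1
93	3	R3_SV_1
93	4	R4_SV_2
36	1	R1_SV_4
36	2	R2_SV_6
36	3	R3_SV_2
36	4	R4_SV_6
37	1	R1_SV_4
37	2	R2_SV_6
37	3	R3_SV_2
37	4	R4_SV_6
46	1	R1_SV_4
46	2	R2_SV_6
46	3	R3_SV_2
46	4	R4_SV_6
53	1	R1_SV_4
53	2	R2_SV_6
53	3	R3_SV_2
53	4	R4_SV_6
63	1	R1_SV_4
63	2	R2_SV_6
63	3	R3_SV_2
63	4	R4_SV_6
74	1	R1_SV_4
74	2	R2_SV_6
74	3	R3_SV_2
74	4	R4_SV_6
78	1	R1_SV_4
78	2	R2_SV_6
78	3	R3_SV_2
78	4	R4_SV_6
30	1	R1_SV_6
30	2	R2_SV_5
30	3	R3_SV_6
30	4	R4_SV_5
33	1	R1_SV_6
33	2	R2_SV_5
33	3	R3_SV_6
33	4	R4_SV_5
70	1	R1_SV_6
70	2	R2_SV_5
70	3	R3_SV_6
70	4	R4_SV_5
80	1	R1_SV_6
80	2	R2_SV_5
80	3	R3_SV_6
80	4	R4_SV_5
89	1	R1_SV_10
89	2	R2_SV_7
89	3	R3_SV_7
89	4	R4_SV_8
94	1	R1_SV_10
94	2	R2_SV_7
94	3	R3_SV_7
94	4	R4_SV_8
96	1	R1_SV_10
96	2	R2_SV_7
96	3	R3_SV_7
96	4	R4_SV_8
72	1	R1_SV_11
72	2	R2_SV_10
72	3	R3_SV_8
72	4	R4_SV_10
91	1	R1_SV_11
91	2	R2_SV_10
91	3	R3_SV_8
91	4	R4_SV_10
95	1	R1_SV_11
95	2	R2_SV_10
95	3	R3_SV_8
95	4	R4_SV_10
41	1	R1_SV_7
41	2	R2_SV_9
41	3	R3_SV_2
41	4	R4_SV_12
51	1	R1_SV_7
51	2	R2_SV_9
51	3	R3_SV_2
51	4	R4_SV_12
31	1	R1_SV_8
31	2	R2_SV_8
31	4	R4_SV_13
76	1	R1_SV_8
76	2	R2_SV_8
76	4	R4_SV_13
20	1	R1_SV_9
20	2	R2_SV_27
20	3	R3_SV_9
20	4	R4_SV_15
88	1	R1_SV_9
88	2	R2_SV_27
88	3	R3_SV_9
88	4	R4_SV_15
16	1	R1_SV_23
16	2	R2_SV_13
16	3	R3_SV_11
16	4	R4_SV_23
22	1	R1_SV_23
22	2	R2_SV_13
22	3	R3_SV_11
22	4	R4_SV_23
18	1	R1_SV_25
18	2	R2_SV_18
18	3	R3_SV_14
18	4	R4_SV_19
24	1	R1_SV_25
24	2	R2_SV_18
24	3	R3_SV_14
24	4	R4_SV_19
49	1	R1_SV_15
49	2	R2_SV_15
49	3	R3_SV_2
49	4	R4_SV_21
68	1	R1_SV_16
68	2	R2_SV_14
68	3	R3_SV_13
68	4	R4_SV_18
52	1	R1_SV_18
52	2	R2_SV_16
52	3	R3_SV_12
52	4	R4_SV_22
01	1	R1_SV_19
01	2	R2_SV_17
01	3	R3_SV_16
01	4	R4_SV_24
56	1	R1_SV_20
56	2	R2_SV_19
56	3	R3_SV_15
56	4	R4_SV_25
25	1	R1_SV_27
25	2	R2_SV_20
25	3	R3_SV_17
25	4	R4_SV_29
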