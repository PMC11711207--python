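node_id,network
0,SMN
1,CO
2,AUD
3,DMN
4,VIS
5,FPN
6,unassigned
7,SUB
8,VAN
9,DAN
10,SMN
11,CO
12,AUD
13,DMN
14,VIS
15,FPN
16,SAL
17,SUB
18,VAN
19,DAN
20,SMN
21,CO
22,AUD
23,unassigned
24,unassigned
25,FPN
26,SAL
27,SUB
28,VAN
29,DAN
30,SMN
31,CO
32,unassigned
33,DMN
34,VIS
35,FPN
36,SAL
37,unassigned
38,VAN
39,DAN
40,SMN
41,CO
42,AUD
43,DMN
44,VIS
45,FPN
46,unassigned
47,SUB
48,VAN
49,DAN
50,SMN
51,CO
52,unassigned
53,DMN
54,VIS
55,FPN
56,SAL
57,SUB
58,VAN
59,DAN
60,SMN
61,CO
62,AUD
63,DMN
64,VIS
65,FPN
66,SAL
67,unassigned
68,VAN
69,DAN
70,SMN
71,CO
72,AUD
73,DMN
74,VIS
75,FPN
76,SAL
77,SUB
78,VAN
79,DAN
80,SMN
81,CO
82,AUD
83,DMN
84,VIS
85,FPN
86,SAL
87,SUB
88,VAN
89,DAN
90,unassigned
91,CO
92,AUD
93,DMN
94,VIS
95,FPN
96,unassigned
97,SUB
98,unassigned
99,DAN
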