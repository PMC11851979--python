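condition_id,complexity,linear,nonlinear,error,n_iv,rt2,mssr_stability,mssr_outperform
1,1,1,1,1,3,0.7193,1000,2500
2,2,1,1,1,3,0.8335,1000,5000
3,3,1,1,1,3,0.8764,1000,1000
4,1,1,2,1,3,0.8639,1000,1000
5,2,1,2,1,3,0.9009,1000,1000
6,3,1,2,1,3,0.9042,1000,1000
7,1,2,1,1,3,0.8161,1000,5000
8,2,2,1,1,3,0.8546,1000,5000
9,3,2,1,1,3,0.8968,1000,1000
10,1,2,2,1,3,0.8941,1000,2500
11,2,2,2,1,3,0.9052,1000,2500
12,3,2,2,1,3,0.9066,1000,2500
13,1,1,1,4,3,0.2422,20000,20000
14,2,1,1,4,3,0.3789,10000,20000
15,3,1,1,4,3,0.7144,1000,1000
16,1,1,2,4,3,0.6901,1000,2500
17,2,1,2,4,3,0.7918,1000,2500
18,3,1,2,4,3,0.8792,1000,1000
19,1,2,1,4,3,0.3228,10000,40000
20,2,2,1,4,3,0.4658,5000,20000
21,3,2,1,4,3,0.6600,1000,5000
22,1,2,2,4,3,0.6840,1000,5000
23,2,2,2,4,3,0.8456,1000,20000
24,3,2,2,4,3,0.8779,1000,1000
25,1,1,1,10,3,0.0273,X,X
26,2,1,1,10,3,0.1006,X,45000
27,3,1,1,10,3,0.3801,10000,5000
28,1,1,2,10,3,0.2037,20000,20000
29,2,1,2,10,3,0.5920,2500,5000
30,3,1,2,10,3,0.7862,1000,1000
31,1,2,1,10,3,0.0571,X,X
32,2,2,1,10,3,0.1021,X,X
33,3,2,1,10,3,0.1788,20000,35000
34,1,2,2,10,3,0.2720,10000,20000
35,2,2,2,10,3,0.4595,5000,10000
36,3,2,2,10,3,0.7874,1000,1000
37,1,1,1,1,5,0.6414,2500,10000
38,2,1,1,1,5,0.8140,1000,2500
39,3,1,1,1,5,0.8874,1000,1000
40,1,1,2,1,5,0.8615,1000,2500
41,2,1,2,1,5,0.8997,1000,2500
42,3,1,2,1,5,0.9019,1000,2500
43,1,2,1,1,5,0.7892,1000,5000
44,2,2,1,1,5,0.8416,1000,10000
45,3,2,1,1,5,0.8809,1000,2500
46,1,2,2,1,5,0.8772,1000,2500
47,2,2,2,1,5,0.8988,1000,2500
48,3,2,2,1,5,0.9034,1000,1000
49,1,1,1,4,5,0.0901,X,X
50,2,1,1,4,5,0.2098,20000,30000
51,3,1,1,4,5,0.5490,5000,2500
52,1,1,2,4,5,0.5162,5000,5000
53,2,1,2,4,5,0.7472,1000,2500
54,3,1,2,4,5,0.8655,1000,2500
55,1,2,1,4,5,0.1650,20000,X
56,2,2,1,4,5,0.4475,2500,20000
57,3,2,1,4,5,0.5848,2500,5000
58,1,2,2,4,5,0.5867,2500,10000
59,2,2,2,4,5,0.7823,1000,2500
60,3,2,2,4,5,0.8758,1000,2500
61,1,1,1,10,5,0.0236,X,X
62,2,1,1,10,5,0.1009,50000,X
63,3,1,1,10,5,0.2910,10000,10000
64,1,1,2,10,5,0.1678,25000,20000
65,2,1,2,10,5,0.4803,5000,10000
66,3,1,2,10,5,0.7546,1000,1000
67,1,2,1,10,5,0.0450,X,X
68,2,2,1,10,5,0.0875,X,X
69,3,2,1,10,5,0.2500,20000,20000
70,1,2,2,10,5,0.2405,20000,20000
71,2,2,2,10,5,0.4895,5000,10000
72,3,2,2,10,5,0.7649,1000,2500
73,1,1,1,1,10,0.5467,2500,20000
74,2,1,1,1,10,0.8163,1000,5000
75,3,1,1,1,10,0.8539,1000,2500
76,1,1,2,1,10,0.8735,1000,2500
77,2,1,2,1,10,0.8920,1000,2500
78,3,1,2,1,10,0.9017,1000,1000
79,1,2,1,1,10,0.7371,5000,50000
80,2,2,1,1,10,0.8356,1000,10000
81,3,2,1,1,10,0.8652,1000,5000
82,1,2,2,1,10,0.8596,1000,5000
83,2,2,2,1,10,0.8965,1000,5000
84,3,2,2,1,10,0.9039,1000,1000
85,1,1,1,4,10,0.0725,X,X
86,2,1,1,4,10,0.3495,10000,25000
87,3,1,1,4,10,0.5593,5000,5000
88,1,1,2,4,10,0.4726,5000,10000
89,2,1,2,4,10,0.7625,1000,5000
90,3,1,2,4,10,0.8517,1000,2500
91,1,2,1,4,10,0.2199,20000,X
92,2,2,1,4,10,0.3829,10000,40000
93,3,2,1,4,10,0.6038,2500,10000
94,1,2,2,4,10,0.5092,5000,20000
95,2,2,2,4,10,0.7743,1000,10000
96,3,2,2,4,10,0.8759,1000,2500
97,1,1,1,10,10,0.0180,X,X
98,2,1,1,10,10,0.0509,X,X
99,3,1,1,10,10,0.1588,40000,X
100,1,1,2,10,10,0.0970,25000,X
101,2,1,2,10,10,0.4152,5000,20000
102,3,1,2,10,10,0.6640,2500,2500
103,1,2,1,10,10,0.0379,X,X
104,2,2,1,10,10,0.1086,X,X
105,3,2,1,10,10,0.1574,35000,X
106,1,2,2,10,10,0.1875,20000,X
107,2,2,2,10,10,0.4790,5000,10000
108,3,2,2,10,10,0.6319,2500,5000
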