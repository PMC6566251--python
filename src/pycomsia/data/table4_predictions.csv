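id,observed,predicted,residual,subset
1,5.331,5.620,-0.29,train
2,6.076,6.034,0.04,test
3,6.893,6.317,0.58,train
4,5.607,5.961,-0.35,test
5,5.558,6.107,-0.55,train
6,5.176,5.295,-0.12,train
7,5.331,5.438,-0.11,train
8,6.456,6.032,0.42,train
9,5.815,6.141,-0.33,test
10,6.310,6.291,0.02,train
11,7.131,6.816,0.31,train
12,7.208,7.689,-0.48,train
13,7.921,7.810,0.11,train
14,7.337,7.386,-0.05,test
15,7.824,7.497,0.33,train
16,8.854,8.718,0.14,train
17,7.921,8.062,-0.14,train
18,8.319,7.972,0.35,train
19,8.432,8.206,0.23,train
20,6.959,7.170,-0.21,test
21,8.770,8.758,0.01,train
22,8.538,8.559,-0.02,train
23,6.921,7.421,-0.50,test
24,8.620,8.273,0.35,train
25,9.036,9.126,-0.09,train
26,8.678,8.415,0.26,train
27,9.174,9.057,0.12,train
28,8.495,8.427,0.07,train
29,8.921,9.236,-0.32,train
30,9.066,8.814,0.25,test
31,7.482,6.743,0.74,train
32,6.818,6.490,0.33,train
33,5.731,6.422,-0.69,train
34,6.762,6.654,0.11,train
35,5.886,6.710,-0.82,train
36,6.714,6.734,-0.02,train
37,6.460,6.848,-0.39,test
38,6.590,6.753,-0.16,train
39,7.499,7.072,0.43,train
40,7.018,6.901,0.12,train
41,6.845,6.878,-0.03,test
42,5.972,6.412,-0.44,train
43,6.079,6.471,-0.39,train
44,7.161,7.148,0.01,train
45,7.574,7.855,-0.28,test
46,8.009,7.774,0.23,test
47,6.575,6.286,0.29,train
48,7.987,7.699,0.29,train
49,7.886,7.915,-0.03,train
50,7.301,7.231,0.07,train
51,5.574,6.018,-0.44,train
52,7.638,7.624,0.01,test
53,5.933,6.164,-0.23,train
54,5.984,5.876,0.11,train
55,6.495,6.381,0.11,train
56,7.155,7.619,-0.46,train
57,6.495,6.436,0.06,train
58,7.155,7.268,-0.11,test
59,7.638,7.512,0.13,train
60,7.444,7.467,-0.02,train
61,7.553,7.408,0.14,train
62,6.854,6.741,0.11,train
63,8.658,8.820,-0.16,train
64,8.824,8.740,0.08,train
65,10.143,10.287,-0.14,train
66,10.602,10.685,-0.08,train
67,10.143,9.759,0.38,test
68,10.097,10.144,-0.05,train
69,8.061,8.023,0.04,train
70,8.114,8.106,0.01,train
71,7.495,7.397,0.10,train
72,6.987,6.787,0.20,train
73,7.553,7.707,-0.15,test
74,7.553,7.757,-0.20,train
75,8.237,7.347,0.89,train
76,5.886,5.739,0.15,train
77,8.174,8.153,0.02,train
78,8.469,8.155,0.31,test
79,7.161,7.463,-0.30,train
80,8.000,8.225,-0.23,train
81,7.658,8.237,-0.58,train
82,9.301,9.394,-0.09,train
83,7.337,7.216,0.12,train
84,7.482,7.278,0.20,test
85,7.000,7.134,-0.13,train
86,7.770,8.110,-0.34,train
87,6.854,6.957,-0.10,train
88,9.000,8.926,0.07,train
89,8.886,8.686,0.20,train
90,9.000,8.960,0.04,train
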