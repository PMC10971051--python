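# Synthetic annual life table (Gompertz-Makeham, A=0.00022, B=2.7e-5, c=1.098),
# calibrated to approximate Australian 2019-2021 sex-averaged mortality.
# Version 1. q_110 forced to 1.
age,qx
0,0.000247
1,0.000250
2,0.000253
3,0.000256
4,0.000259
5,0.000263
6,0.000267
7,0.000272
8,0.000277
9,0.000283
10,0.000289
11,0.000295
12,0.000303
13,0.000311
14,0.000320
15,0.000330
16,0.000340
17,0.000352
18,0.000365
19,0.000379
20,0.000395
21,0.000412
22,0.000431
23,0.000452
24,0.000474
25,0.000499
26,0.000527
27,0.000557
28,0.000590
29,0.000626
30,0.000666
31,0.000710
32,0.000758
33,0.000810
34,0.000868
35,0.000932
36,0.001001
37,0.001078
38,0.001162
39,0.001254
40,0.001355
41,0.001466
42,0.001589
43,0.001723
44,0.001870
45,0.002031
46,0.002209
47,0.002403
48,0.002617
49,0.002852
50,0.003109
51,0.003392
52,0.003702
53,0.004043
54,0.004416
55,0.004827
56,0.005277
57,0.005771
58,0.006314
59,0.006909
60,0.007562
61,0.008278
62,0.009065
63,0.009927
64,0.010874
65,0.011911
66,0.013050
67,0.014298
68,0.015667
69,0.017168
70,0.018814
71,0.020617
72,0.022593
73,0.024759
74,0.027131
75,0.029729
76,0.032574
77,0.035687
78,0.039095
79,0.042822
80,0.046898
81,0.051354
82,0.056222
83,0.061538
84,0.067341
85,0.073672
86,0.080573
87,0.088092
88,0.096276
89,0.105178
90,0.114851
91,0.125352
92,0.136739
93,0.149071
94,0.162408
95,0.176812
96,0.192342
97,0.209057
98,0.227012
99,0.246258
100,0.266838
101,0.288788
102,0.312133
103,0.336885
104,0.363037
105,0.390566
106,0.419424
107,0.449539
108,0.480809
109,0.513102
110,1.000000
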