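age,qx
40,0.0025
41,0.002722
42,0.002963
43,0.003226
44,0.003512
45,0.003824
46,0.004163
47,0.004533
48,0.004935
49,0.005372
50,0.005849
51,0.006368
52,0.006933
53,0.007548
54,0.008218
55,0.008947
56,0.00974
57,0.010605
58,0.011545
59,0.01257
60,0.013685
61,0.014899
62,0.016221
63,0.01766
64,0.019227
65,0.020932
66,0.022789
67,0.024811
68,0.027012
69,0.029409
70,0.032018
71,0.034858
72,0.037951
73,0.041318
74,0.044983
75,0.048974
76,0.053319
77,0.058049
78,0.063199
79,0.068806
80,0.07491
81,0.081556
82,0.088791
83,0.096669
84,0.105245
85,0.114582
86,0.124747
87,0.135815
88,0.147864
89,0.160982
90,0.175264
91,0.190812
92,0.207741
93,0.226171
94,0.246236
95,0.268081
96,0.291865
97,0.317758
98,0.345949
99,0.37664
100,0.410055
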