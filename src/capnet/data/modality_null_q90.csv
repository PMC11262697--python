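n,kuiper_q90,dip_q90
5,0.583333,0.166667
6,0.500000,0.166667
7,0.500000,0.142857
8,0.458333,0.125000
9,0.416667,0.122222
10,0.400000,0.120000
11,0.393939,0.136364
12,0.333333,0.125000
13,0.358974,0.115385
14,0.345238,0.107143
15,0.333333,0.100000
16,0.312500,0.106250
17,0.313725,0.111765
18,0.305556,0.111111
19,0.298246,0.105263
20,0.283333,0.100000
21,0.273810,0.095238
22,0.272727,0.090909
23,0.275362,0.095652
24,0.250000,0.100000
25,0.260000,0.100000
26,0.250000,0.096154
27,0.250000,0.092593
28,0.238095,0.089286
29,0.238506,0.086207
30,0.233333,0.088889
31,0.228495,0.090323
32,0.229167,0.093750
33,0.220455,0.090909
34,0.220588,0.088235
35,0.214286,0.085714
36,0.222222,0.083333
37,0.207207,0.081792
38,0.210526,0.084211
39,0.205128,0.086538
40,0.200000,0.087500
41,0.203252,0.085366
42,0.202381,0.083333
43,0.193798,0.081395
44,0.196970,0.079545
45,0.188889,0.077778
46,0.188406,0.079710
47,0.182624,0.080851
48,0.187500,0.083333
49,0.178571,0.081633
50,0.183333,0.080000
51,0.181373,0.078431
52,0.179487,0.076923
53,0.176101,0.075472
54,0.175926,0.076389
55,0.175758,0.077273
56,0.172619,0.080357
57,0.171053,0.078947
58,0.169540,0.077586
59,0.163842,0.076271
60,0.166667,0.075000
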