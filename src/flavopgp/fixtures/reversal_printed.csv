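treatment_id,rf_mdr1,rf_kb,rf_cross
negative_control,1.000,1.000,4.338
elacridar,6.818,1.512,0.962
1,1.307,0.720,2.390
2,1.965,1.169,2.582
3,1.963,1.077,2.380
4,3.443,0.749,0.943
5,1.127,0.790,3.041
6,1.646,0.274,0.722
7,1.841,0.780,1.839
8,3.613,1.731,2.079
9,4.586,1.053,0.996
10,0.962,0.361,1.627
11,0.526,0.523,4.310
12,0.564,0.916,7.046
13,2.126,0.791,1.613
14,1.989,0.931,2.030
15,1.073,0.542,2.192
16,1.260,0.508,1.748
17,0.580,1.391,10.414
18,2.556,0.781,1.325
19,1.042,0.366,1.524
20,1.140,1.261,4.799
21,1.352,0.545,1.749
22,1.107,0.293,1.149
23,1.494,2.138,6.205
24,1.489,0.473,1.377
25,1.308,0.264,0.877
26,1.188,0.635,2.317
27,1.740,0.744,1.854
28,0.704,3.531,21.773
29,0.799,0.299,1.623
30,2.448,1.561,2.767
31,1.039,0.294,1.228
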