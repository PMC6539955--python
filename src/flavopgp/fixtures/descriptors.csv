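compound_id,vsurf_DW23,e_sol,dipole,vsurf_G
1,0.707,-3.559,0.841,1.252
2,1.000,-3.054,1.237,1.295
3,1.000,-3.711,0.896,1.288
4,1.581,-2.211,1.348,1.326
5,1.000,-1.574,0.972,1.351
6,3.391,-0.953,1.133,1.335
7,1.000,-4.867,1.158,1.244
8,0.707,-2.935,1.161,1.259
9,1.000,-4.269,1.262,1.240
10,1.000,-5.855,0.829,1.262
11,14.221,-5.762,0.769,1.275
12,1.118,-11.881,0.997,1.322
13,0.707,1.216,0.776,1.409
14,0.707,-0.596,0.679,1.256
15,0.707,-0.369,0.420,1.293
16,0.500,1.410,0.440,1.275
17,11.597,-0.871,0.438,1.283
18,0.866,-3.328,1.024,1.284
19,3.606,0.379,0.434,1.300
20,0.500,-0.215,0.446,1.297
21,1.581,0.317,1.021,1.410
22,1.000,-2.655,0.523,1.258
23,1.000,-2.064,0.551,1.264
24,0.500,-0.711,0.690,1.293
25,1.118,-3.043,0.796,1.278
26,1.000,-1.461,0.793,1.292
27,1.000,-3.440,1.426,1.416
28,16.523,-1.351,0.657,1.244
29,1.000,-4.664,0.811,1.339
30,0.500,-5.127,1.167,1.253
31,1.000,-5.328,1.082,1.277
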