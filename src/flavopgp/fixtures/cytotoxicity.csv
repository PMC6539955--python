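treatment_id,cell_line,ic50_mean,ic50_sd
negative_control,KB_MDR1,3.102,0.441
negative_control,KB,0.715,0.056
elacridar,KB_MDR1,0.473,0.005
elacridar,KB,0.455,0.036
1,KB_MDR1,2.373,0.970
1,KB,0.993,0.127
2,KB_MDR1,1.579,0.05
2,KB,0.612,0.107
3,KB_MDR1,1.580,0.23
3,KB,0.664,0.051
4,KB_MDR1,0.901,0.042
4,KB,0.955,0.007
5,KB_MDR1,2.752,0.211
5,KB,0.905,0.035
6,KB_MDR1,1.884,0.243
6,KB,2.610,0.671
7,KB_MDR1,1.685,0.623
7,KB,0.916,0.048
8,KB_MDR1,0.859,0.137
8,KB,0.413,0.099
9,KB_MDR1,0.676,0.035
9,KB,0.679,0.023
10,KB_MDR1,3.226,0.068
10,KB,1.983,0.078
11,KB_MDR1,5.894,0.083
11,KB,1.368,0.077
12,KB_MDR1,5.501,0.672
12,KB,0.781,0.133
13,KB_MDR1,1.459,0.529
13,KB,0.904,0.158
14,KB_MDR1,1.560,0.258
14,KB,0.768,0.113
15,KB_MDR1,2.891,0.100
15,KB,1.319,0.041
16,KB_MDR1,2.463,0.320
16,KB,1.409,0.225
17,KB_MDR1,5.353,0.001
17,KB,0.514,0.006
18,KB_MDR1,1.214,0.219
18,KB,0.916,0.064
19,KB_MDR1,2.976,0.035
19,KB,1.953,0.197
20,KB_MDR1,2.721,0.067
20,KB,0.567,0.069
21,KB_MDR1,2.295,0.054
21,KB,1.312,0.114
22,KB_MDR1,2.803,0.203
22,KB,2.439,0.189
23,KB_MDR1,2.076,0.041
23,KB,0.335,0.015
24,KB_MDR1,2.084,0.146
24,KB,1.513,0.057
25,KB_MDR1,2.371,0.106
25,KB,2.703,0.182
26,KB_MDR1,2.611,0.116
26,KB,1.127,0.092
27,KB_MDR1,1.783,0.055
27,KB,0.962,0.019
28,KB_MDR1,4.409,0.540
28,KB,0.203,0.093
29,KB_MDR1,3.882,0.172
29,KB,2.393,0.313
30,KB_MDR1,1.267,0.108
30,KB,0.458,0.072
31,KB_MDR1,2.986,0.298
31,KB,2.432,0.227
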