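compound_id,ic50_experimental,ic50_predicted,residual
1,2.373,2.180,0.193
2,1.579,1.252,0.327
3,1.580,2.490,-0.910
4,0.901,1.026,-0.125
5,2.752,2.149,0.603
6,1.884,1.684,0.200
7,1.685,1.612,0.073
8,0.859,1.009,-0.150
9,0.676,1.025,-0.349
10,3.226,3.196,0.030
11,5.894,5.914,-0.020
12,5.501,5.494,0.007
13,1.459,2.336,-0.877
14,1.560,1.670,-0.110
15,2.891,2.808,0.083
16,2.463,1.874,0.589
17,5.353,4.819,0.534
18,1.214,1.878,-0.664
19,2.976,3.101,-0.125
20,2.721,2.671,0.050
21,2.295,2.055,0.240
22,2.803,2.982,-0.179
23,2.076,2.740,-0.664
24,2.084,2.032,0.052
25,2.371,2.483,-0.112
26,2.611,2.054,0.557
27,1.783,2.071,-0.288
28,4.409,4.782,-0.373
29,3.882,3.652,0.230
30,1.267,1.681,-0.414
31,2.986,2.369,0.617
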