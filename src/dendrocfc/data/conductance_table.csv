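level,g_NaF,g_NaP,g_KDR,g_KC,g_KA,g_KM,g_K2,g_CaH,g_CaL,g_h_exp,g_h_unif,g_h_0
0,0,5,450,0,6,600,15,0,0,0,0,0
1,0,5,450,0,6,300,15,0,0,0,0,0
2,0,5,750,288,200,250,15,16,1,1,1,0
3,0,0.6,250,288,40,136,0,16,1,1.7635,1,0
4,0,0.12,0,9,40,136,0,16,1,2.4515,1,0
5,0,0.12,0,9,40,136,0,16,1,3.3194,1,0
6,0,1.2,500,288,40,136,15,16,1,1.7635,1,0
7,0,0.6,150,288,40,136,15,16,1,2.4515,1,0
8,0,0.12,2,9,40,136,15,16,1,3.3194,1,0
9,0,0.12,2,9,40,40,0,4,1,4.4141,1,0
10,0,0.12,2,9,40,40,0,4,1,5.7950,1,0
11,0,0.12,2,9,40,40,0,4,1,7.5368,1,0
12,0,0.12,2,9,40,40,0,4,1,9.7338,1,0
13,0,0.12,2,9,40,40,0,4,1,12.5050,1,0
14,0,0.12,2,9,40,40,0,4,1,16.0006,1,0
15,0,0.024,2,9,40,40,0,4,1,20.4098,1,0
16,0,0.024,2,9,40,10,10,4,1,25.9714,1,0
17,0,0.024,2,9,40,10,10,4,1,32.9866,1,0
18,0,0.024,2,9,40,10,10,4,1,41.8355,1,0
19,0,0.024,2,9,40,10,10,10.8,1,52.9971,2,0
20,0,0.024,2,9,40,10,10,2.4,1,52.9971,2,0
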