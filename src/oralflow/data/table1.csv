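id,kappa,n,score_mean,score_sem,set_label
1,0.026,0.55,2.09,0.17,set1
2,0.025,0.60,2.92,0.25,set1
3,0.068,0.55,4.25,0.21,set1
4,0.590,0.26,3.81,0.29,set1
5,0.330,0.31,3.85,0.26,set1
6,0.636,0.28,4.73,0.25,set1
7,0.410,0.35,4.63,0.17,set1
8,1.000,0.27,5.30,0.24,set1
9,0.057,0.48,2.89,0.21,set2
10,0.198,0.44,4.41,0.22,set2
11,0.130,0.43,3.20,0.25,set2
12,0.170,0.46,4.69,0.21,set2
13,0.040,0.57,3.26,0.25,set2
14,0.270,0.42,5.04,0.17,set2
15,0.03,0.65,3.3,1.0,set3
16,0.14,0.52,3.4,0.8,set3
17,0.35,0.40,4.1,0.8,set3
18,7.00,0.25,9.4,0.4,set3
19,22.0,0.17,11.7,0.2,set3
20,31.0,0.17,12.0,0.2,set3
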