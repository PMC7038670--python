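subject,sex,age,height_cm,weight_kg,sbp_mae,sbp_sd,dbp_mae,dbp_sd
1,male,58,180,90,1.34,0.07,1.61,0.16
2,female,57,150,68,1.51,0.13,1.92,0.22
3,male,60,170,80,1.46,0.17,1.87,0.29
4,female,36,155,66,1.62,0.21,2.01,0.38
5,male,31,168,65,1.24,0.27,1.56,0.39
6,male,36,175,90,1.44,0.33,1.64,0.66
7,male,27,175,68,1.47,0.22,1.77,0.52
8,female,27,156,55,1.70,0.42,2.06,0.71
9,female,24,160,90,1.39,0.35,1.72,0.66
10,male,28,180,110,1.58,0.44,1.95,0.77
11,male,36,176,105,1.22,0.21,1.84,0.51
12,female,27,163,55,1.38,0.19,1.79,0.44
13,female,27,164,61,1.66,0.47,1.68,0.41
14,male,27,168,68,1.53,0.38,1.72,0.49
15,male,27,165,79,1.47,0.24,1.76,0.39
16,male,27,168,72,1.51,0.26,1.89,0.44
17,male,27,170,68,1.42,0.33,1.77,0.46
18,female,59,156,71,1.45,0.22,1.87,0.34
19,female,54,154,50,1.38,0.28,1.92,0.44
20,male,23,168,66,1.54,0.36,1.86,0.55
21,male,27,163,62,1.58,0.32,1.83,0.51
22,male,23,178,72,1.56,0.28,1.78,0.61
23,male,20,173,68,1.33,0.15,1.82,0.53
24,female,21,160,58,1.49,0.24,1.79,0.46
25,female,27,160,54,1.62,0.33,1.96,0.61
26,male,20,175,53,1.84,0.37,1.77,0.55
27,male,20,174,105,1.58,0.41,2.07,0.66
28,male,23,183,71,1.77,0.55,1.88,0.73
29,male,20,170,85,1.67,0.41,1.83,0.55
30,female,20,155,61,1.89,0.43,1.88,0.62
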