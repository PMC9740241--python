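bos_score,fractured_6mo
3.0,1
3.52,1
4.05,1
4.58,1
5.1,1
5.62,1
6.15,1
6.68,1
7.2,1
5.0,0
5.18,0
5.37,0
5.55,0
5.74,0
5.92,0
6.11,0
6.29,0
6.48,0
6.66,0
6.85,0
7.03,0
7.22,0
7.4,0
7.6,0
7.77,0
7.94,0
8.11,0
8.27,0
8.44,0
8.61,0
8.78,0
8.95,0
9.12,0
9.28,0
9.45,0
9.62,0
9.79,0
9.96,0
10.13,0
10.29,0
10.46,0
10.63,0
10.8,0
10.97,0
11.14,0
11.31,0
11.47,0
11.64,0
11.81,0
11.98,0
12.15,0
12.32,0
12.48,0
12.65,0
12.82,0
12.99,0
13.16,0
13.33,0
13.49,0
13.66,0
13.83,0
14.0,0
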