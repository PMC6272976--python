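run,A,B,C,D,E,F,G,H,D1,D2,D3,EA,EA_sd,BM,BM_sd
1,2.5,1.5,0.5,2,25,0.3,0.1,0.1,-1,1,-1,250.12,1.27,0.428,0.005
2,1,1.5,1.5,1,25,0.3,0.3,0.1,-1,-1,1,215.21,1.17,0.402,0.006
3,2.5,0.5,1.5,2,10,0.3,0.3,0.3,-1,-1,-1,234.12,1.73,0.473,0.011
4,1,1.5,0.5,2,25,0.1,0.3,0.3,1,-1,-1,181.25,1.58,0.39,0.008
5,1,0.5,1.5,1,25,0.3,0.1,0.3,1,1,-1,191.25,2.93,0.385,0.009
6,1,0.5,0.5,2,10,0.3,0.3,0.1,1,1,1,123.41,1.38,0.418,0.010
7,2.5,0.5,0.5,1,25,0.1,0.3,0.3,-1,1,1,245.28,0.72,0.403,0.008
8,2.5,1.5,0.5,1,10,0.3,0.1,0.3,1,-1,1,221.32,2.01,0.471,0.006
9,2.5,1.5,1.5,1,10,0.1,0.3,0.1,1,1,-1,231.55,1.48,0.489,0.012
10,1,1.5,1.5,2,10,0.1,0.1,0.3,-1,1,1,164.25,1.53,0.431,0.007
11,2.5,0.5,1.5,2,25,0.1,0.1,0.1,1,-1,1,253.32,1.77,0.428,0.010
12,1,0.5,0.5,1,10,0.1,0.1,0.1,-1,-1,-1,118.35,0.71,0.419,0.011
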