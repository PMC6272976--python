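run,X1,X2,X3,X4,EA,EA_sd,BM,BM_sd
1,-1,-1,0,0,240.99,1.33,0.405,0.006
2,1,-1,0,0,174.26,1.80,0.448,0.010
3,-1,1,0,0,217.43,0.86,0.386,0.008
4,1,1,0,0,241.56,1.71,0.39,0.007
5,0,0,-1,-1,150.97,1.55,0.472,0.011
6,0,0,1,-1,218.21,1.42,0.481,0.004
7,0,0,-1,1,217.54,0.90,0.483,0.023
8,0,0,1,1,105.86,0.86,0.494,0.006
9,-1,0,0,-1,180.70,0.82,0.447,0.005
10,1,0,0,-1,235.65,1.38,0.488,0.012
11,-1,0,0,1,250.14,2.00,0.481,0.008
12,1,0,0,1,140.93,0.94,0.469,0.008
13,0,-1,-1,0,235.93,0.69,0.422,0.006
14,0,1,-1,0,200.45,1.07,0.387,0.013
15,0,-1,1,0,188.06,1.06,0.431,0.020
16,0,1,1,0,212.07,1.16,0.398,0.009
17,-1,0,-1,0,194.38,1.00,0.443,0.009
18,1,0,-1,0,230.18,1.21,0.451,0.008
19,-1,0,1,0,220.04,1.41,0.455,0.015
20,1,0,1,0,146.33,0.97,0.493,0.021
21,0,-1,0,-1,185.89,1.69,0.439,0.011
22,0,1,0,-1,208.25,0.49,0.380,0.007
23,0,-1,0,1,163.21,1.94,0.440,0.008
24,0,1,0,1,193.42,0.73,0.430,0.005
25,0,0,0,0,270.32,1.05,0.519,0.018
26,0,0,0,0,271.85,0.62,0.520,0.020
27,0,0,0,0,269.09,0.97,0.521,0.015
28,0,0,0,0,260.33,1.12,0.513,0.011
29,0,0,0,0,259.36,0.89,0.516,0.017
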